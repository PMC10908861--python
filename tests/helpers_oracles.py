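"""Independent brute-force oracles used to cross-check package computations.

These deliberately re-derive quantities by enumeration rather than calling
the implementation paths they validate.
"""

from __future__ import annotations

import itertools
import math


def regions_of(per_codon: list[int]) -> list[list[int]]:
    """Explicit region lists: 1 codon per region when N > L, else floor(L/N)
    codons per region, final partial region kept."""
    n = sum(per_codon)
    L = len(per_codon)
    rlen = 1 if n > L else L // n
    return [per_codon[i : i + rlen] for i in range(0, L, rlen)]


def entropy_of(counts: list[int]) -> float:
    n = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h


def max_entropy_bruteforce(n: int, m: int) -> float:
    """Maximum entropy over ALL integer placements of n reads in m regions,
    found by exhaustive enumeration of compositions (small n, m only)."""
    best = 0.0
    for comp in itertools.product(range(n + 1), repeat=m - 1):
        if sum(comp) > n:
            continue
        alloc = list(comp) + [n - sum(comp)]
        best = max(best, entropy_of(alloc))
    return best


def pme_oracle(per_codon: list[int]) -> float:
    """PME from explicit region lists and brute-force maximum entropy."""
    region_sums = [sum(r) for r in regions_of(per_codon)]
    h = entropy_of(region_sums)
    h_max = max_entropy_bruteforce(sum(per_codon), len(region_sums))
    if h_max == 0.0:
        return 1.0
    return h / h_max


def length_fdr_oracle(null_lengths: list[int], observed: int) -> float:
    """Direct strict-count definition of the length FDR."""
    return sum(1 for l in null_lengths if l > observed) / len(null_lengths)


def expected_length_oracle(null_lengths: list[int], alpha: float) -> int:
    """Exhaustive scan of the FDR step function for the smallest passing length."""
    for l in range(0, max(null_lengths) + 1):
        if length_fdr_oracle(null_lengths, l) <= alpha:
            return l
    return max(null_lengths)


_KOZAK_TABLE = {
    -6: {"G": 3},
    -5: {"C": 1},
    -4: {"C": 1},
    -3: {"G": 3, "A": 3},
    -2: {"C": 1},
    -1: {"C": 1},
    1: {"G": 3},
}


def kozak_oracle(context7: str) -> int:
    """Score a 7-mer (positions -6..-1 then +1) by direct table lookup."""
    assert len(context7) == 7
    positions = [-6, -5, -4, -3, -2, -1, 1]
    return sum(_KOZAK_TABLE[p].get(b, 0) for p, b in zip(positions, context7))


def aug_orf_lengths_oracle(seq: str) -> list[int]:
    """Re-derive AUG-ORF lengths by scanning codons downstream of every ATG."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in stops:
                out.append((j - i) // 3)
                break
            j += 3
    return out
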