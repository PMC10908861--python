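"""ORF-length null model from randomized pseudo-transcripts.

Long ORFs arise rarely by chance; how rarely depends on transcript length
and nucleotide composition.  For a transcript of length T we build a null
by generating pseudo-transcripts of the same length — permutations of the
transcript sequence and/or windows sampled from the genome — and
enumerating every AUG-initiated ORF (ATG to next in-frame stop, all three
frames, nested starts each counted).  With n pooled pseudo-ORFs of which m
are strictly longer than the observed ORF, the length FDR is m/n.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .annotation_io import GenomeSequence, STOP_CODONS

log = logging.getLogger(__name__)


def _as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def shuffle_sequence(seq: str, rng: int | np.random.Generator | None = None) -> str:
    """Uniform random permutation of the nucleotides (composition preserved)."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    rng = _as_rng(rng)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return b"".join(rng.permutation(arr)).decode()


def dinucleotide_shuffle(
    seq: str, rng: int | np.random.Generator | None = None, max_tries: int = 10_000
) -> str:
    """Dinucleotide-frequency-preserving shuffle (Eulerian-walk resampling).

    Available for sensitivity analysis; the default null uses the plain
    mononucleotide permutation.  Successor lists are shuffled and walked;
    dead-ended walks (incomplete Eulerian paths) are rejected and retried.
    """
    rng = _as_rng(rng)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    base_succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        base_succ.setdefault(a, []).append(b)
    for _ in range(max_tries):
        succ = {
            a: [bs[i] for i in rng.permutation(len(bs))]
            for a, bs in base_succ.items()
        }
        counts = {a: 0 for a in succ}
        out = [seq[0]]
        ok = True
        for _ in range(len(seq) - 1):
            a = out[-1]
            if counts[a] >= len(succ[a]):
                ok = False  # walk dead-ended before consuming every edge
                break
            out.append(succ[a][counts[a]])
            counts[a] += 1
        if ok:
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")


def sample_genomic_background(
    genome: GenomeSequence,
    length: int,
    rng: int | np.random.Generator | None = None,
    max_tries: int = 50,
) -> str:
    """A uniformly sampled contiguous N-free genomic window of the given length."""
    rng = _as_rng(rng)
    chroms = [c for c in genome.chroms if genome.chrom_length(c) >= length]
    if not chroms:
        raise ValueError(f"no chromosome long enough for a {length}-nt window")
    weights = np.array([genome.chrom_length(c) - length + 1 for c in chroms], float)
    weights /= weights.sum()
    for _ in range(max_tries):
        c = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, genome.chrom_length(c) - length + 1))
        window = genome.fetch(c, start, start + length)
        if "N" not in window:
            return window
    raise ValueError(f"no N-free window of length {length} found in {max_tries} tries")


def aug_orf_lengths(seq: str) -> list[int]:
    """Lengths (codons, stop excluded) of every ATG->stop ORF in all 3 frames."""
    n = len(seq)
    out: list[int] = []
    for frame in range(3):
        stops = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        for i in range(frame, n - 2, 3):
            if seq[i : i + 3] != "ATG":
                continue
            k = bisect.bisect_left(stops, i + 3)
            if k < len(stops):
                out.append((stops[k] - i) // 3)
    return out


@dataclass
class NullLengthDistribution:
    """Pooled pseudo-ORF lengths (aa) for one transcript length."""

    transcript_length: int
    orf_lengths: np.ndarray
    n_shuffle: int = 0  # ORFs contributed by shuffled-sequence pseudo-transcripts
    n_genomic: int = 0  # ORFs contributed by genomic-background pseudo-transcripts
    source: str = "synthetic"
    _sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.orf_lengths = np.asarray(self.orf_lengths, dtype=np.int64)
        if (self.orf_lengths < 1).any():
            raise ValueError("pseudo-ORF lengths must be >= 1 codon")
        self._sorted = np.sort(self.orf_lengths)

    @property
    def n(self) -> int:
        return len(self.orf_lengths)

    def to_tsv(self, path) -> None:
        lengths, counts = np.unique(self.orf_lengths, return_counts=True)
        with open(path, "w") as fh:
            fh.write(
                f"# transcript_length={self.transcript_length}\t"
                f"n_shuffle={self.n_shuffle}\tn_genomic={self.n_genomic}\t"
                f"source={self.source}\n"
            )
            fh.write("length_aa\tcount\n")
            for l, c in zip(lengths, counts):
                fh.write(f"{l}\t{c}\n")


def build_null(
    transcript_length: int,
    tx_sequence: str | None = None,
    genome: GenomeSequence | None = None,
    n_pseudo: int = 1000,
    rng: int | np.random.Generator | None = None,
    source: str = "synthetic",
    shuffle: str = "mono",
) -> NullLengthDistribution:
    """Pool AUG-ORF lengths over pseudo-transcripts from both randomization sources.

    ``n_pseudo`` pseudo-transcripts are drawn per available source (shuffled
    copies of ``tx_sequence`` and/or genomic windows of the same length);
    their expected ORFs are merged for the final FDR.
    """
    if tx_sequence is None and genome is None:
        raise ValueError("need a transcript sequence and/or a genome to randomize")
    rng = _as_rng(rng)
    shuffler = shuffle_sequence if shuffle == "mono" else dinucleotide_shuffle
    lengths: list[int] = []
    n_shuffle = n_genomic = 0
    if tx_sequence is not None:
        if len(tx_sequence) != transcript_length:
            raise ValueError("tx_sequence length != transcript_length")
        for _ in range(n_pseudo):
            ls = aug_orf_lengths(shuffler(tx_sequence, rng))
            lengths.extend(ls)
            n_shuffle += len(ls)
    if genome is not None:
        for _ in range(n_pseudo):
            ls = aug_orf_lengths(
                sample_genomic_background(genome, transcript_length, rng)
            )
            lengths.extend(ls)
            n_genomic += len(ls)
    return NullLengthDistribution(
        transcript_length, np.array(lengths, dtype=np.int64),
        n_shuffle=n_shuffle, n_genomic=n_genomic, source=source,
    )


def pooled_null_from_sequences(
    sequences: list[str], transcript_length: int, source: str = "synthetic"
) -> NullLengthDistribution:
    """Null from explicitly supplied pseudo-transcript sequences (i.i.d. draws)."""
    lengths: list[int] = []
    for s in sequences:
        lengths.extend(aug_orf_lengths(s))
    return NullLengthDistribution(
        transcript_length, np.array(lengths, dtype=np.int64),
        n_genomic=len(lengths), source=source,
    )


def stop_probability(composition: tuple[float, float, float, float]) -> float:
    """P(random codon is a stop) for i.i.d. (A, C, G, T) frequencies."""
    a, c, g, t = composition
    return t * a * a + t * a * g + t * g * a  # TAA + TAG + TGA


def geometric_expected_length(
    alpha: float,
    p_stop: float,
    max_codons: int | None = None,
) -> float:
    """Closed-form expected null ORF length at FDR alpha for i.i.d. sequences.

    In the infinite-transcript limit ORF lengths are geometric with per-codon
    stop probability ``p_stop`` and the expected length is
    ln(alpha)/ln(1 - p_stop).  On a finite transcript the downstream window
    of each start is truncated, which shortens the null; passing
    ``max_codons`` (about transcript_length/3 per frame) evaluates that
    finite-length form: with start windows m = 1..M equally likely,
    FDR(l) = sum_{m>l} (q^l - q^m) / sum_m (1 - q^m), q = 1 - p_stop.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = 1.0 - p_stop
    if max_codons is None:
        return math.log(alpha) / math.log(q)
    ms = np.arange(1, max_codons + 1)
    denom = float((1.0 - q**ms).sum())
    for l in range(0, max_codons + 1):
        tail = float((q**l - q ** ms[ms > l]).sum()) / denom
        if tail <= alpha:
            return float(l)
    return float(max_codons)


def orf_length_fdr(null: NullLengthDistribution, observed_length_aa: int) -> float:
    """FDR = (# pseudo-ORFs strictly longer than observed) / n."""
    if null.n == 0:
        raise ValueError("empty null distribution")
    m = null.n - int(np.searchsorted(null._sorted, observed_length_aa, side="right"))
    return m / null.n


def expected_length_at_fdr(null: NullLengthDistribution, alpha: float) -> int:
    """Smallest integer length (aa) whose length FDR is <= alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if null.n == 0:
        raise ValueError("empty null distribution")
    if orf_length_fdr(null, 0) <= alpha:
        return 0
    for l in np.unique(null._sorted):
        if orf_length_fdr(null, int(l)) <= alpha:
            return int(l)
    return int(null._sorted[-1])  # unreachable: FDR(max) = 0
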