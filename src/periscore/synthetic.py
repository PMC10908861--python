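"""Synthetic genomes, transcriptomes and ribosome-profiling reads.

The generator emulates the statistical structure the translation classifier
detects: transcripts with 5'UTR/CDS/3'UTR architecture and planted
noncanonical ORFs; A-site positions multinomial over codons (a Dirichlet
concentration controls positional uniformity) and over the three codon
positions with a configurable in-frame bias; "localized-artifact" loci that
pile all reads on at most two positions (the PME < 0.1 negative class); and
5' ends back-computed from A-sites through a per-fragment-length offset so
the QC stage can re-derive the offsets.  Truth tables record every planted
ORF with its signal class so recovery tests never reparse generator
internals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomeSequence,
    ReadAlignment,
    STOP_CODONS,
    Transcript,
    reverse_complement,
)

BASES = "ACGT"

#: human-mRNA-like i.i.d. base frequencies (A, C, G, T), GC ~= 47%
DEFAULT_COMPOSITION = (0.265, 0.235, 0.235, 0.265)


@dataclass
class ReadModel:
    """Read-generation parameters for translated/untranslated loci."""

    depth: float = 60.0  # mean reads per ORF (Poisson)
    frame_bias: tuple[float, float, float] = (0.75, 0.15, 0.10)
    uniformity_alpha: float = 5.0  # Dirichlet concentration over codons
    initiation_boost: float = 0.08  # extra read fraction paused at the first body codon
    length_offsets: dict[int, int] = field(
        default_factory=lambda: {28: 15, 29: 15, 30: 16}
    )
    length_probs: dict[int, float] = field(
        default_factory=lambda: {28: 0.5, 29: 0.3, 30: 0.2}
    )
    background_reads_per_tx: float = 15.0  # frame-uniform noise over the transcript

    def __post_init__(self) -> None:
        if abs(sum(self.frame_bias) - 1.0) > 1e-9:
            raise ValueError("frame_bias must sum to 1")
        if set(self.length_offsets) != set(self.length_probs):
            raise ValueError("length_offsets and length_probs must share keys")
        if abs(sum(self.length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("length_probs must sum to 1")


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic benchmark."""

    n_transcripts: int = 40
    composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION
    utr5_range: tuple[int, int] = (120, 180)  # nt
    cds_aa_range: tuple[int, int] = (100, 200)  # residues incl. Met
    utr3_range: tuple[int, int] = (100, 160)  # nt
    uorf_prob: float = 0.9
    uorf_aa_range: tuple[int, int] = (10, 30)
    dorf_prob: float = 0.6
    dorf_aa_range: tuple[int, int] = (8, 20)
    translated_prob: float = 0.6  # planted ncORF translated (periodic signal)
    artifact_prob: float = 0.15  # else: localized-artifact locus
    lncrna_frac: float = 0.1
    lncrna_orf_aa_range: tuple[int, int] = (15, 40)
    two_exon_prob: float = 0.3
    intron_range: tuple[int, int] = (60, 120)
    minus_strand_prob: float = 0.5
    flank: int = 60  # genomic padding around each gene
    reads: ReadModel = field(default_factory=ReadModel)

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")


def _as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_genome(
    length: int,
    composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION,
    rng: int | np.random.Generator | None = None,
) -> str:
    """An i.i.d. nucleotide sequence with the given (A, C, G, T) frequencies."""
    rng = _as_rng(rng)
    if length < 0:
        raise ValueError("length must be >= 0")
    p = np.asarray(composition, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("composition must be a probability vector")
    idx = rng.choice(4, size=length, p=p)
    return np.frombuffer(BASES.encode(), dtype=np.uint8)[idx].tobytes().decode()


def _nonstop_codons(n: int, rng: np.random.Generator, p: np.ndarray) -> str:
    """n codons drawn i.i.d. from the composition, stop codons rejected."""
    out = []
    while len(out) < n:
        c = "".join(BASES[i] for i in rng.choice(4, size=3, p=p))
        if c not in STOP_CODONS:
            out.append(c)
    return "".join(out)


def _orf_sequence(aa: int, rng: np.random.Generator, p: np.ndarray) -> str:
    """ATG + (aa-1) non-stop codons + a stop codon: encodes ``aa`` residues."""
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + _nonstop_codons(aa - 1, rng, p) + stop


def _signal(spec: SimulationSpec, rng: np.random.Generator) -> tuple[bool, str]:
    u = rng.random()
    if u < spec.translated_prob:
        return True, "periodic"
    if u < spec.translated_prob + spec.artifact_prob:
        return False, "localized"
    return False, "uniform"


def simulate_transcriptome(
    spec: SimulationSpec,
    rng: int | np.random.Generator | None = None,
) -> tuple[list[Transcript], GenomeSequence, pd.DataFrame]:
    """Transcript models with planted ORFs, their genome, and a truth table.

    Each gene sits on its own chromosome with ``spec.flank`` nt of padding;
    a fraction of models are two-exon and/or minus-strand to exercise the
    coordinate maps.  Truth rows: (transcript_id, orf_type, start, end,
    translated, signal) in transcript coordinates.
    """
    rng = _as_rng(rng)
    p = np.asarray(spec.composition, dtype=float)
    n_lnc = int(round(spec.n_transcripts * spec.lncrna_frac))
    transcripts: list[Transcript] = []
    chroms: dict[str, str] = {}
    truth_rows: list[dict] = []
    max_off = max(spec.reads.length_offsets.values())

    for i in range(spec.n_transcripts):
        tid = f"TX{i + 1:04d}"
        is_lnc = i < n_lnc
        planted: list[tuple[str, int, int]] = []  # (orf_type, start, end)
        if is_lnc:
            lead = int(rng.integers(*spec.utr5_range))
            aa = int(rng.integers(*spec.lncrna_orf_aa_range))
            orf = _orf_sequence(aa, rng, p)
            tail = int(rng.integers(*spec.utr3_range))
            seq = (
                simulate_genome(lead, spec.composition, rng)
                + orf
                + simulate_genome(tail, spec.composition, rng)
            )
            planted.append(("lncRNA-ORF", lead, lead + len(orf)))
            cds = None
            biotype = "lncRNA"
        else:
            utr5 = list(simulate_genome(int(rng.integers(*spec.utr5_range)), spec.composition, rng))
            aa = int(rng.integers(*spec.cds_aa_range))
            cds_seq = _orf_sequence(aa, rng, p)
            utr3 = list(simulate_genome(int(rng.integers(*spec.utr3_range)), spec.composition, rng))
            if rng.random() < spec.uorf_prob:
                uaa = int(rng.integers(*spec.uorf_aa_range))
                uspan = 3 * (uaa + 1)
                lo = max_off + 2  # keep 5' ends of uORF reads on the transcript
                hi = len(utr5) - uspan
                if hi > lo:
                    ustart = int(rng.integers(lo, hi))
                    utr5[ustart : ustart + uspan] = _orf_sequence(uaa, rng, p)
                    planted.append(("uORF", ustart, ustart + uspan))
            if rng.random() < spec.dorf_prob:
                daa = int(rng.integers(*spec.dorf_aa_range))
                dspan = 3 * (daa + 1)
                hi = len(utr3) - dspan - 3
                if hi > 3:
                    dstart = int(rng.integers(3, hi))
                    utr3[dstart : dstart + dspan] = _orf_sequence(daa, rng, p)
                    planted.append(("dORF", dstart, dstart + dspan))
            utr5_s, utr3_s = "".join(utr5), "".join(utr3)
            seq = utr5_s + cds_seq + utr3_s
            cds = (len(utr5_s), len(utr5_s) + len(cds_seq))
            planted = [
                (t, s + (len(utr5_s) + len(cds_seq) if t == "dORF" else 0),
                 e + (len(utr5_s) + len(cds_seq) if t == "dORF" else 0))
                for t, s, e in planted
            ]
            biotype = "protein_coding"

        strand = "-" if rng.random() < spec.minus_strand_prob else "+"
        two_exon = rng.random() < spec.two_exon_prob and len(seq) > 60
        flank = spec.flank
        if two_exon:
            cut = int(rng.integers(30, len(seq) - 30))
            intron = simulate_genome(int(rng.integers(*spec.intron_range)), spec.composition, rng)
            layout = (
                simulate_genome(flank, spec.composition, rng)
                + seq[:cut]
                + intron
                + seq[cut:]
                + simulate_genome(flank, spec.composition, rng)
            )
            exons_plus = [
                (flank, flank + cut),
                (flank + cut + len(intron), flank + cut + len(intron) + len(seq) - cut),
            ]
        else:
            layout = (
                simulate_genome(flank, spec.composition, rng)
                + seq
                + simulate_genome(flank, spec.composition, rng)
            )
            exons_plus = [(flank, flank + len(seq))]
        if strand == "+":
            chrom_seq, exons = layout, exons_plus
        else:
            chrom_seq = reverse_complement(layout)
            n = len(layout)
            exons = sorted((n - b, n - a) for a, b in exons_plus)
        chrom = f"chr_{tid}"
        chroms[chrom] = chrom_seq
        tx = Transcript(
            tid, f"G{i + 1:04d}", biotype, chrom, strand, exons, cds=cds, sequence=seq
        )
        transcripts.append(tx)
        if cds is not None:
            translated, signal = True, "periodic"
            truth_rows.append(
                {
                    "transcript_id": tid, "orf_type": "canonical",
                    "start": cds[0], "end": cds[1],
                    "translated": translated, "signal": signal,
                }
            )
        for orf_type, s, e in planted:
            if orf_type == "canonical":
                continue
            translated, signal = _signal(spec, rng)
            truth_rows.append(
                {
                    "transcript_id": tid, "orf_type": orf_type,
                    "start": s, "end": e,
                    "translated": translated, "signal": signal,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "orf_type", "start", "end", "translated", "signal"],
    )
    return transcripts, GenomeSequence(chroms), truth


def simulate_ribo_reads(
    transcripts: list[Transcript],
    truth: pd.DataFrame,
    read_model: ReadModel,
    rng: int | np.random.Generator | None = None,
) -> list[ReadAlignment]:
    """Reads for every truth locus plus frame-uniform background noise.

    Periodic loci draw A-site codons from a Dirichlet-multinomial over the
    ORF body and codon positions from the frame bias; uniform loci spread
    A-sites evenly over all three frames; localized loci use <= 2 positions.
    The emitted record is the biological 5' end (A-site minus the
    fragment-length offset, in transcript space) mapped to the genome.
    """
    rng = _as_rng(rng)
    by_id = {tx.transcript_id: tx for tx in transcripts}
    lengths = sorted(read_model.length_offsets)
    probs = np.array([read_model.length_probs[l] for l in lengths])
    bias = np.asarray(read_model.frame_bias)
    reads: list[ReadAlignment] = []

    def emit(tx: Transcript, tpos_arr: np.ndarray) -> None:
        ls = rng.choice(len(lengths), size=len(tpos_arr), p=probs)
        for tpos, li in zip(tpos_arr, ls):
            frag = lengths[li]
            t5 = int(tpos) - read_model.length_offsets[frag]
            if t5 < 0 or tpos >= tx.length:
                continue
            reads.append(
                ReadAlignment(tx.chrom, tx.to_genome(t5), frag, tx.strand)
            )

    for row in truth.itertuples(index=False):
        if row.signal == "none":
            continue
        tx = by_id[row.transcript_id]
        s, e = int(row.start), int(row.end)
        L = (e - s) // 3 - 1
        n = int(rng.poisson(read_model.depth))
        if n == 0 or L < 1:
            continue
        if row.signal == "periodic":
            w = rng.dirichlet(np.full(L, read_model.uniformity_alpha))
            codons = rng.choice(L, size=n, p=w)
            # initiation pausing enriches the first body codon (the classic
            # metagene peak one codon into the ORF)
            n_init = rng.binomial(n, read_model.initiation_boost)
            if n_init:
                codons[:n_init] = 0
            offs = rng.choice(3, size=n, p=bias)
            tpos = s + 3 * (codons + 1) + offs
        elif row.signal == "uniform":
            tpos = s + rng.integers(0, e - s, size=n)
        elif row.signal == "localized":
            # footprint pile-up: <= 2 adjacent positions within one codon
            codon = int(rng.integers(1, L + 1))
            k = int(rng.integers(1, 3))
            tpos = s + 3 * codon + rng.integers(0, k, size=n)
        else:
            raise ValueError(f"unknown signal class {row.signal!r}")
        emit(tx, np.asarray(tpos))

    max_off = max(read_model.length_offsets.values())
    for tx in transcripts:
        n = int(rng.poisson(read_model.background_reads_per_tx))
        if n == 0 or tx.length <= max_off + 1:
            continue
        tpos = rng.integers(max_off, tx.length, size=n)
        emit(tx, tpos)
    return reads


# ---------------------------------------------------------------------------
# PepScore feature simulation
# ---------------------------------------------------------------------------


def simulate_pepscore_features(
    n_pos: int,
    n_neg: int,
    rng: int | np.random.Generator | None = None,
    t1_shift: float = 2.0,
    t2_odds: float = 5.0,
    t3_shift: float = 1.0,
) -> pd.DataFrame:
    """Class-conditional (t1, t2, t3) draws mirroring stable-vs-undetectable
    microprotein structure: stable peptides have more significant length FDRs
    (t1 shifted up), more domains (odds multiplied), and higher conservation
    (t3 shifted up).  Zero effects give exchangeable classes (AUROC ~ 0.5)."""
    rng = _as_rng(rng)
    base_domain_p = 0.15
    odds = base_domain_p / (1 - base_domain_p) * t2_odds
    pos_domain_p = odds / (1 + odds)

    def draw(n: int, shift1: float, p2: float, shift3: float, label: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t1": np.abs(rng.normal(0.7, 1.2, size=n)) + shift1,
                "t2": rng.binomial(1, p2, size=n).astype(float),
                "t3": rng.normal(-0.5 + shift3, 1.5, size=n),
                "label": label,
            }
        )

    pos = draw(n_pos, t1_shift, pos_domain_p, t3_shift, 1)
    neg = draw(n_neg, 0.0, base_domain_p, 0.0, 0)
    return pd.concat([pos, neg], ignore_index=True)


def simulate_logistic_dataset(
    n: int,
    beta: tuple[float, float, float] = (0.8, 1.5, 0.6),
    intercept: float = -1.0,
    rng: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """(t1, t2, t3, label) drawn from a known logistic model, for
    coefficient-recovery tests."""
    rng = _as_rng(rng)
    x = pd.DataFrame(
        {
            "t1": rng.gamma(2.0, 1.0, size=n),
            "t2": rng.binomial(1, 0.3, size=n).astype(float),
            "t3": rng.normal(0.0, 1.0, size=n),
        }
    )
    z = intercept + x.to_numpy() @ np.asarray(beta)
    x["label"] = rng.binomial(1, 1.0 / (1.0 + np.exp(-z)))
    return x
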