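"""Candidate ORF enumeration, periodicity features and the translation classifier.

The classifier asks whether A-site-adjusted reads within a candidate ORF show
continuous 3-nt periodicity.  For an ORF of L codons (excluding the start
codon) with per-codon counts (n_i1, n_i2, n_i3) on the three nucleotides of
codon i:

* ``f1`` — fraction of all reads on the 1st nucleotide of codons;
* ``f2`` — fraction of codons where the 1st nucleotide strictly out-counts
  both the 2nd and 3rd;
* ``f3`` (PME, percentage of maximum entropy) — Shannon entropy of the read
  distribution over codon regions divided by the entropy of the most even
  integer placement of the same reads, so 1 means uniform coverage and
  values near 0 mean the signal is localised to a few positions.

A logistic regression on (f1, f2, f3) is trained with canonical ORFs as
positives and internal off-frame ORFs plus highly localised (f3 < 0.1)
candidates as negatives; calls are retained when at least two independent
models assign probability > 0.6 and the ORF is expressed (RPKM > 0.2) in at
least one cell type.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    STOP_CODONS,
    AsitePosition,
    Transcript,
    TranscriptIndex,
)

log = logging.getLogger(__name__)

DEFAULT_START_CODONS = ("ATG", "CTG", "GTG", "TTG", "ATC")  # NUG + AUC
ORF_TYPES = (
    "canonical",
    "truncated/extended-canonical",
    "uORF",
    "ouORF",
    "iORF",
    "dORF",
    "odORF",
    "lncRNA-ORF",
    "pseudogene-ORF",
)


@dataclass
class CandidateORF:
    """A (start, stop) interval on a transcript; ``end`` is one past the stop codon."""

    transcript_id: str
    start: int
    end: int
    start_codon: str
    orf_type: str | None = None
    frame_vs_cds: str | None = None
    total_reads: int = 0

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0 or self.end - self.start < 6:
            raise ValueError("ORF span must be a multiple of 3 and >= 6 nt")

    @property
    def length_aa(self) -> int:
        """Peptide length in aa; the start codon encodes the first residue."""
        return (self.end - self.start) // 3 - 1

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"


@dataclass
class CodonReadMatrix:
    """Per-codon A-site read counts (n_i1, n_i2, n_i3) for codons i=1..L.

    The L rows cover the ORF *excluding the start codon* (the stop codon row
    is included, so L = span/3 - 1).
    """

    counts: np.ndarray  # shape (L, 3)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3 or self.counts.shape[0] < 1:
            raise ValueError("counts must be an (L, 3) array with L >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def L(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_profile(cls, per_nt: np.ndarray, start: int, end: int) -> "CodonReadMatrix":
        """Build from a per-nucleotide transcript count vector and ORF bounds."""
        body = np.asarray(per_nt[start + 3 : end])
        return cls(body.reshape(-1, 3))


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def feature_f1(m: CodonReadMatrix) -> float:
    """Fraction of reads on the 1st nucleotide of codons."""
    if m.N == 0:
        raise ValueError("f1 undefined for N = 0 (filter by min_reads first)")
    return float(m.counts[:, 0].sum()) / m.N


def feature_f2(m: CodonReadMatrix) -> float:
    """Fraction of codons whose 1st nucleotide strictly out-counts the 2nd and 3rd."""
    c = m.counts
    wins = (c[:, 0] > c[:, 1]) & (c[:, 0] > c[:, 2])
    return float(np.count_nonzero(wins)) / m.L


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _region_sums(per_codon: np.ndarray, region_len: int) -> np.ndarray:
    L = len(per_codon)
    m = (L + region_len - 1) // region_len
    return np.array(
        [per_codon[j * region_len : (j + 1) * region_len].sum() for j in range(m)]
    )


def most_even_allocation(n: int, m: int) -> np.ndarray:
    """The most even integer split of n reads over m regions (counts differ by <= 1)."""
    q, k = divmod(n, m)
    return np.array([q + 1] * k + [q] * (m - k))


def feature_pme(m: CodonReadMatrix, inframe_only: bool = False) -> float:
    """Percentage of maximum entropy of the read distribution over codon regions.

    Region length is 1 codon when N > L, else floor(L/N); the final partial
    region is retained.  The maximum entropy is that of the most even integer
    placement of the N reads over the regions.
    """
    per_codon = m.counts[:, 0] if inframe_only else m.counts.sum(axis=1)
    N = int(per_codon.sum())
    L = m.L
    if N == 0:
        raise ValueError("PME undefined for N = 0")
    region_len = 1 if N > L else L // N
    regions = _region_sums(per_codon, region_len)
    h = _entropy(regions / N)
    h_max = _entropy(most_even_allocation(N, len(regions)) / N)
    if h_max == 0.0:
        return 1.0  # a single region cannot deviate from uniformity
    return float(min(h / h_max, 1.0))


def periodicity_features(m: CodonReadMatrix, inframe_only_pme: bool = False):
    return feature_f1(m), feature_f2(m), feature_pme(m, inframe_only_pme)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


def enumerate_candidates(
    tx: Transcript,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    asite_counts: np.ndarray | None = None,
    min_reads: int | None = None,
) -> list[CandidateORF]:
    """All (start codon, next in-frame stop) pairs in the three frames.

    Nested starts each open their own ORF; ORFs without an in-frame stop are
    dropped, as are candidates whose start or stop codon contains N.  When
    ``asite_counts`` (per-nucleotide transcript counts) is given, total reads
    are annotated and ``min_reads`` is applied as a strict lower bound.
    """
    seq = tx.sequence
    if seq is None:
        raise ValueError(f"{tx.transcript_id}: sequence required for enumeration")
    starts = set(start_codons)
    n = len(seq)
    out: list[CandidateORF] = []
    for frame in range(3):
        stop_pos = [
            i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS
        ]
        si = 0
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon not in starts or "N" in codon:
                continue
            while si < len(stop_pos) and stop_pos[si] < i + 3:
                si += 1
            # si is monotone in i within a frame; rescan from the current point
            j = None
            for sp in stop_pos[si:]:
                if sp >= i + 3:
                    j = sp
                    break
            if j is None:
                continue
            orf = CandidateORF(tx.transcript_id, i, j + 3, codon)
            if asite_counts is not None:
                orf.total_reads = int(np.asarray(asite_counts[i : j + 3]).sum())
                if min_reads is not None and not orf.total_reads > min_reads:
                    continue
            out.append(orf)
    out.sort(key=lambda o: (o.start, o.end))
    return out


def classify_orf_type(orf: CandidateORF, tx: Transcript) -> str:
    """Deterministic ORF-type label relative to the transcript's annotated CDS.

    Noncoding biotypes label by biotype alone; on coding transcripts the
    label partitions by position and frame relative to the CDS (the uORF /
    ouORF / iORF / odORF / dORF scheme), with AUG-sharing-stop variants kept
    as truncated/extended-canonical.
    """
    bt = tx.biotype.lower()
    if "lnc" in bt or bt in ("lincrna", "antisense"):
        return "lncRNA-ORF"
    if "pseudogene" in bt:
        return "pseudogene-ORF"
    if tx.cds is None:
        raise ValueError(f"{tx.transcript_id}: protein_coding transcript lacks a CDS")
    cs, ce = tx.cds
    s, e = orf.start, orf.end
    in_frame = (s - cs) % 3 == 0
    if (s, e) == (cs, ce):
        return "canonical"
    if e == ce and in_frame:
        return "truncated/extended-canonical"
    if e <= cs:
        return "uORF"
    if s >= ce:
        return "dORF"
    if s < cs:
        return "ouORF"
    if e <= ce:
        return "iORF"
    return "odORF"


def frame_vs_cds(orf: CandidateORF, tx: Transcript) -> str:
    if tx.cds is None:
        return "n/a"
    return "in-frame" if (orf.start - tx.cds[0]) % 3 == 0 else "off-frame"


# ---------------------------------------------------------------------------
# read placement and the per-transcript feature table
# ---------------------------------------------------------------------------


def asite_count_vectors(
    transcripts: Sequence[Transcript],
    positions: Iterable[AsitePosition],
    index: TranscriptIndex | None = None,
) -> dict[str, np.ndarray]:
    """Per-transcript per-nucleotide A-site count vectors (non-exonic positions drop)."""
    if index is None:
        index = TranscriptIndex(transcripts)
    vecs = {tx.transcript_id: np.zeros(tx.length, dtype=np.int64) for tx in transcripts}
    for p in positions:
        for tx, tpos in index.hits(p.chrom, p.strand, p.pos):
            vecs[tx.transcript_id][tpos] += 1
    return vecs


def annotate_candidate_orfs(
    transcripts: Sequence[Transcript],
    asite_vectors: Mapping[str, np.ndarray],
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    min_reads: int = 10,
    inframe_only_pme: bool = False,
) -> pd.DataFrame:
    """Enumerate, filter (> min_reads) and featurise candidate ORFs.

    Returns one row per candidate with coordinates, type label and
    (f1, f2, f3).
    """
    rows = []
    for tx in transcripts:
        vec = asite_vectors.get(tx.transcript_id)
        if vec is None:
            continue
        for orf in enumerate_candidates(tx, start_codons, vec, min_reads):
            m = CodonReadMatrix.from_profile(vec, orf.start, orf.end)
            if m.N == 0:  # all reads sat on the start codon
                continue
            f1, f2, f3 = periodicity_features(m, inframe_only_pme)
            rows.append(
                {
                    "orf_id": orf.orf_id,
                    "transcript_id": tx.transcript_id,
                    "start": orf.start,
                    "end": orf.end,
                    "start_codon": orf.start_codon,
                    "length_aa": orf.length_aa,
                    "orf_type": classify_orf_type(orf, tx),
                    "frame_vs_cds": frame_vs_cds(orf, tx),
                    "total_reads": orf.total_reads,
                    "f1": f1,
                    "f2": f2,
                    "f3": f3,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "orf_id", "transcript_id", "start", "end", "start_codon", "length_aa",
            "orf_type", "frame_vs_cds", "total_reads", "f1", "f2", "f3",
        ],
    )


# ---------------------------------------------------------------------------
# training set, model, consensus, expression
# ---------------------------------------------------------------------------


def assemble_training_set(
    orf_table: pd.DataFrame,
    n_pos: int = 1000,
    n_neg: int = 3000,
    rng_seed: int | np.random.Generator = 0,
    pme_negative_max: float = 0.1,
    exclude: pd.Index | None = None,
) -> pd.DataFrame:
    """Sample labelled (f1, f2, f3) rows for classifier training.

    Positives are canonical ORFs; the negative pool is internal off-frame
    ORFs plus any candidate with f3 below ``pme_negative_max`` (highly
    localised coverage).  Sampling is uniform without replacement; a
    shortfall takes everything available with a logged warning.  ``exclude``
    removes rows (by index) already used, e.g. by a prior training draw, so
    a disjoint test set can be assembled.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    table = orf_table if exclude is None else orf_table.drop(index=exclude)
    pos_pool = table[table["orf_type"] == "canonical"]
    neg_mask = (
        (table["orf_type"] == "iORF") & (table["frame_vs_cds"] == "off-frame")
    ) | (table["f3"] < pme_negative_max)
    neg_pool = table[neg_mask & (table["orf_type"] != "canonical")]

    def draw(pool: pd.DataFrame, k: int, what: str) -> pd.DataFrame:
        if len(pool) < k:
            log.warning("only %d %s available (requested %d)", len(pool), what, k)
            return pool
        idx = rng.choice(len(pool), size=k, replace=False)
        return pool.iloc[np.sort(idx)]

    pos = draw(pos_pool, n_pos, "positive examples").assign(label=1)
    neg = draw(neg_pool, n_neg, "negative examples").assign(label=0)
    return pd.concat([pos, neg])


@dataclass
class TranslationModel:
    """Logistic regression over (f1, f2, f3) with training metadata."""

    intercept: float
    coef: dict[str, float]
    model_id: str = "merged"
    n_pos: int = 0
    n_neg: int = 0
    cv_folds: int = 5
    cv_auroc: float | None = None
    test_auroc: float | None = None
    features: tuple[str, ...] = ("f1", "f2", "f3")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = features[list(self.features)].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("non-finite feature values")
        beta = np.array([self.coef[f] for f in self.features])
        z = self.intercept + x @ beta
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coef": self.coef,
                    "model_id": self.model_id,
                    "n_pos": self.n_pos,
                    "n_neg": self.n_neg,
                    "cv_folds": self.cv_folds,
                    "cv_auroc": self.cv_auroc,
                    "test_auroc": self.test_auroc,
                    "features": list(self.features),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "TranslationModel":
        with open(path) as fh:
            d = json.load(fh)
        d["features"] = tuple(d["features"])
        return cls(**d)


def train_translation_model(
    train: pd.DataFrame,
    test: pd.DataFrame | None = None,
    cv_folds: int = 5,
    rng_seed: int = 0,
    model_id: str = "merged",
    features: Sequence[str] = ("f1", "f2", "f3"),
) -> TranslationModel:
    """Fit the periodicity logistic model with k-fold CV and held-out AUROC.

    ``train``/``test`` are labelled feature tables (column ``label`` in
    {0, 1}); both classes must be present in ``train``.  A mild L2 penalty
    (C=10) keeps the fit defined when the periodicity features separate the
    classes completely — common on clean data, where the unpenalized MLE
    diverges and coefficient signs become arbitrary — while leaving the
    predicted probabilities decisive.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    x = train[list(features)].to_numpy(dtype=float)
    clf = LogisticRegression(C=10.0, solver="lbfgs", max_iter=1000)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    cv_auroc = float(np.mean(cross_val_score(clf, x, y, cv=cv, scoring="roc_auc")))
    clf.fit(x, y)
    model = TranslationModel(
        intercept=float(clf.intercept_[0]),
        coef={f: float(c) for f, c in zip(features, clf.coef_[0])},
        model_id=model_id,
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        cv_folds=cv_folds,
        cv_auroc=cv_auroc,
    )
    if test is not None and len(test) and test["label"].nunique() == 2:
        model.test_auroc = float(
            roc_auc_score(test["label"].to_numpy(), model.predict(test))
        )
    return model


def predict_translation(model: TranslationModel, features: pd.DataFrame) -> np.ndarray:
    return model.predict(features)


def consensus_calls(
    probabilities: pd.DataFrame,
    min_support: int = 2,
    p_threshold: float = 0.6,
) -> pd.Series:
    """Retain ORFs with >= min_support models assigning probability > p_threshold."""
    support = (probabilities > p_threshold).sum(axis=1)
    return support >= min_support


def orf_rpkm(orf_reads: int, orf_length_nt: int, library_size: int) -> float:
    """Reads per kilobase of ORF per million mapped reads."""
    if orf_length_nt <= 0:
        raise ValueError("zero-length ORF")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return orf_reads / (orf_length_nt / 1000.0) / (library_size / 1e6)


def expression_filter(
    rpkm_by_celltype: Sequence[float] | Mapping[str, float],
    threshold: float = 0.2,
) -> bool:
    """True when any cell type exceeds the RPKM threshold (strict)."""
    values = (
        list(rpkm_by_celltype.values())
        if isinstance(rpkm_by_celltype, Mapping)
        else list(rpkm_by_celltype)
    )
    return any(v > threshold for v in values)


# ---------------------------------------------------------------------------
# BED12 export
# ---------------------------------------------------------------------------


def orfs_to_bed12(
    orf_table: pd.DataFrame,
    transcripts: Sequence[Transcript],
    path,
) -> None:
    """Write called ORFs as genomic BED12 (blocks follow the exon structure)."""
    by_id = {tx.transcript_id: tx for tx in transcripts}
    with open(path, "w") as fh:
        for _, row in orf_table.iterrows():
            tx = by_id[row["transcript_id"]]
            gpos = sorted(tx.to_genome(t) for t in range(row["start"], row["end"]))
            blocks: list[tuple[int, int]] = []
            a = prev = gpos[0]
            for g in gpos[1:]:
                if g != prev + 1:
                    blocks.append((a, prev + 1))
                    a = g
                prev = g
            blocks.append((a, prev + 1))
            chrom_start, chrom_end = blocks[0][0], blocks[-1][1]
            sizes = ",".join(str(b - a) for a, b in blocks)
            starts = ",".join(str(a - chrom_start) for a, _ in blocks)
            fh.write(
                "\t".join(
                    [
                        tx.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        str(row["orf_id"]),
                        "0",
                        tx.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
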