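"""PepScore: probability that a noncanonical peptide is stably expressed.

The model is a logistic regression over three ORF features:

* ``t1 = -log10(length FDR)`` with the empirical FDR floored at
  1/(n_null + 1) so an observed ORF longer than every pseudo-ORF still
  scores finitely;
* ``t2`` — 1 if the peptide carries a Pfam or transmembrane (TMHMM) domain
  hit (consumed from a precomputed table), else 0;
* ``t3 = log10(|sum f_i| + 1) * sign(sum f_i)`` where f_i are per-codon
  in-frame PhyloCSF conservation scores.

Scores above 0.6 (strict) flag peptides as likely stable.  The model is
defined for AUG-initiated ORFs; scoring non-AUG ORFs requires ``force``.

Auxiliary per-ORF sequence annotations used alongside the model live here
too: the additive 0-13 Kozak-context score, the optimal-codon fraction,
overlapping amino-acid category fractions, and the Tau tissue-specificity
index.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import STOP_CODONS

log = logging.getLogger(__name__)

OPTIMAL_CODONS = frozenset(
    {
        "GCC", "CGC", "AAC", "GAC", "TGC", "CAG", "GAG", "GGC", "CAC",
        "CTG", "AAG", "CCC", "TTC", "AGC", "ACC", "TAC", "GTG",
    }
)

AA_CATEGORIES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("FLIVPAG"),
    "charged": frozenset("RKDE"),
    "polar": frozenset("QNHSTC"),
    "hydrophilic": frozenset("CDEHKNQR"),
    "amphipathic": frozenset("WYM"),
}

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# (position relative to the A of AUG, required base(s), contribution)
_KOZAK_RULES: tuple[tuple[int, str, int], ...] = (
    (-6, "G", 3),
    (-5, "C", 1),
    (-4, "C", 1),
    (-3, "GA", 3),
    (-2, "C", 1),
    (-1, "C", 1),
    (+1, "G", 3),
)


# ---------------------------------------------------------------------------
# the three model features
# ---------------------------------------------------------------------------


def feature_t1(fdr: float, n_null: int) -> float:
    """-log10 of the length FDR, floored at the add-one pseudocount 1/(n_null+1)."""
    if not 0 <= fdr <= 1:
        raise ValueError("FDR must be in [0, 1]")
    if n_null <= 0:
        raise ValueError("n_null must be positive")
    return -math.log10(max(fdr, 1.0 / (n_null + 1)))


def feature_t2(domain_table: Mapping[str, Iterable[str]], orf_id: str) -> int:
    """1 iff the ORF has >= 1 Pfam or TMHMM domain hit; absent IDs count as 0."""
    if orf_id not in domain_table:
        log.info("ORF %s absent from domain table; t2 = 0", orf_id)
        return 0
    hits = domain_table[orf_id]
    return 1 if any(True for _ in hits) else 0


def feature_t3(per_codon_scores: Sequence[float]) -> float:
    """Signed log conservation: log10(|sum f_i| + 1) * sign(sum f_i)."""
    scores = np.asarray(per_codon_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty per-codon score vector")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite conservation scores")
    s = float(scores.sum())
    return math.log10(abs(s) + 1.0) * float(np.sign(s))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class PepScoreModel:
    intercept: float
    coef: dict[str, float]
    n_train: int = 0
    n_test: int = 0
    cv_folds: int = 5
    cv_auroc: float | None = None
    test_auroc: float | None = None
    features: tuple[str, ...] = ("t1", "t2", "t3")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in features.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {', '.join(missing)}")
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
                    "n_train": self.n_train,
                    "n_test": self.n_test,
                    "cv_folds": self.cv_folds,
                    "cv_auroc": self.cv_auroc,
                    "test_auroc": self.test_auroc,
                    "features": list(self.features),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "PepScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        d["features"] = tuple(d["features"])
        return cls(**d)


def _stratified_split(
    labels: np.ndarray,
    n_train: int,
    n_test: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/test index draws, class proportions preserved."""
    idx = np.arange(len(labels))
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        members = rng.permutation(idx[labels == cls])
        frac = len(members) / len(labels)
        k_tr = int(round(n_train * frac))
        k_te = int(round(n_test * frac))
        if k_tr + k_te > len(members):
            k_tr = min(k_tr, len(members))
            k_te = len(members) - k_tr
            log.warning("class %s: shortfall, using %d train / %d test", cls, k_tr, k_te)
        train_parts.append(members[:k_tr])
        test_parts.append(members[k_tr : k_tr + k_te])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def train_pepscore(
    features: pd.DataFrame,
    labels: Sequence[int] | None = None,
    n_train: int = 200,
    n_test: int = 100,
    cv_folds: int = 5,
    rng_seed: int = 0,
    stratified: bool = True,
    feature_names: Sequence[str] = ("t1", "t2", "t3"),
) -> PepScoreModel:
    """Fit the stability logistic model on a labelled microprotein table.

    ``n_train`` examples are drawn (stratified by class by default) for
    5-fold cross-validated fitting and a disjoint ``n_test`` set for the
    held-out AUROC, mirroring a curated-collection protocol where the
    labelled pool exceeds the sampled sizes.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    y = (
        features["label"].to_numpy()
        if labels is None
        else np.asarray(list(labels), dtype=int)
    )
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(rng_seed)
    if stratified:
        tr_idx, te_idx = _stratified_split(y, n_train, n_test, rng)
    else:
        perm = rng.permutation(len(y))
        tr_idx, te_idx = perm[:n_train], perm[n_train : n_train + n_test]
    x = features[list(feature_names)].to_numpy(dtype=float)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    cv_auroc = float(
        np.mean(cross_val_score(clf, x[tr_idx], y[tr_idx], cv=cv, scoring="roc_auc"))
    )
    clf.fit(x[tr_idx], y[tr_idx])
    model = PepScoreModel(
        intercept=float(clf.intercept_[0]),
        coef={f: float(c) for f, c in zip(feature_names, clf.coef_[0])},
        n_train=len(tr_idx),
        n_test=len(te_idx),
        cv_folds=cv_folds,
        cv_auroc=cv_auroc,
    )
    if len(te_idx):
        scores = model.predict(features.iloc[te_idx])
        if len(np.unique(y[te_idx])) == 2:
            model.test_auroc = float(roc_auc_score(y[te_idx], scores))
    return model


def score_peptides(
    model: PepScoreModel,
    features: pd.DataFrame,
    threshold: float = 0.6,
    force: bool = False,
) -> pd.DataFrame:
    """Score peptides and flag high-PepScore ones (score > threshold, strict).

    The model is defined for AUG-initiated ORFs: if the table carries a
    ``start_codon`` column, non-ATG rows are refused unless ``force``.
    """
    if "start_codon" in features.columns and not force:
        bad = features.loc[features["start_codon"] != "ATG"]
        if len(bad):
            raise ValueError(
                f"{len(bad)} non-AUG ORF(s) in input; PepScore is defined for "
                "AUG starts (pass force=True to override)"
            )
    out = features.copy()
    out["pepscore"] = model.predict(features)
    out["high_pepscore"] = out["pepscore"] > threshold
    return out


# ---------------------------------------------------------------------------
# auxiliary sequence annotations
# ---------------------------------------------------------------------------


def kozak_score(context_upstream: str, plus1: str) -> int:
    """Additive start-context score in 0..13.

    ``context_upstream`` holds up to 6 nt immediately 5' of the AUG
    (positions -6..-1, given 5'->3'; shorter contexts score the available
    positions only), and ``plus1`` the first nucleotide after the AUG.
    Contributions: G at -6 (+3), C at -5/-4 (+1 each), G or A at -3 (+3),
    C at -2/-1 (+1 each), G at +1 (+3).
    """
    context_upstream = context_upstream.upper()
    plus1 = plus1.upper()
    if len(context_upstream) > 6 or len(plus1) > 1:
        raise ValueError("context is at most 6 nt upstream + 1 nt downstream")
    for ch in context_upstream + plus1:
        if ch not in "ACGTN":
            raise ValueError(f"non-ACGTN character {ch!r} in Kozak context")
    if len(context_upstream) < 6:
        log.info("Kozak context shorter than 6 nt; scoring available positions only")
    by_pos = {-(len(context_upstream) - i): b for i, b in enumerate(context_upstream)}
    if plus1:
        by_pos[+1] = plus1
    score = 0
    for pos, bases, pts in _KOZAK_RULES:
        b = by_pos.get(pos)
        if b is not None and b in bases:
            score += pts
    return score


def kozak_score_at(sequence: str, start: int) -> int:
    """Kozak score for an AUG at transcript position ``start``."""
    upstream = sequence[max(0, start - 6) : start]
    plus1 = sequence[start + 3 : start + 4]
    return kozak_score(upstream, plus1)


def optimal_codon_fraction(orf_nt_sequence: str) -> float:
    """Fraction of non-stop codons (start included) in the optimized-codon list."""
    seq = orf_nt_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError("ORF length must be divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    coding = [c for c in codons if c not in STOP_CODONS]
    if not coding:
        return 0.0
    return sum(c in OPTIMAL_CODONS for c in coding) / len(coding)


def aa_category_fractions(peptide: str) -> dict[str, float]:
    """Per-category residue fractions; categories overlap so sums can exceed 1."""
    peptide = peptide.upper()
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValueError(f"nonstandard residue(s): {sorted(bad)}")
    n = len(peptide)
    return {
        cat: sum(aa in members for aa in peptide) / n
        for cat, members in AA_CATEGORIES.items()
    }


def tau_index(x: Sequence[float]) -> float:
    """Tau tissue-specificity index: 0 = uniform expression, 1 = single-tissue.

    tau = sum(1 - x_i / max(x)) / (n - 1).  Returns NaN for an all-zero
    profile (undefined).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("need an expression vector over >= 2 tissues")
    if (arr < 0).any():
        raise ValueError("expression values must be >= 0")
    mx = arr.max()
    if mx == 0:
        return float("nan")
    r = arr / mx
    return float((1.0 - r).sum() / (len(arr) - 1))
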