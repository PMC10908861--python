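"""End-to-end ORF calling: QC -> A-site adjustment -> features -> consensus.

One model is trained per read sample (cell type) plus one on the merged
reads; an ORF is called when at least ``min_support`` models assign
translation probability above ``p_threshold`` and the ORF is expressed
(RPKM above ``rpkm_threshold``) in at least one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import ReadAlignment, Transcript, TranscriptIndex
from .orf_caller import (
    CodonReadMatrix,
    DEFAULT_START_CODONS,
    TranslationModel,
    annotate_candidate_orfs,
    asite_count_vectors,
    assemble_training_set,
    consensus_calls,
    expression_filter,
    orf_rpkm,
    periodicity_features,
    train_translation_model,
)
from .readqc import OffsetTable, adjust_to_asite, calibrate_offsets

log = logging.getLogger(__name__)


@dataclass
class CallResult:
    orf_table: pd.DataFrame  # candidates + features + per-model P + flags
    models: dict[str, TranslationModel]
    offsets: dict[str, OffsetTable]
    library_sizes: dict[str, int]


def features_for_orfs(
    orf_table: pd.DataFrame,
    asite_vectors: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """(f1, f2, f3) for a fixed candidate set under another sample's counts.

    Rows with no reads in the ORF body get NaN features (the sample then
    contributes no positive prediction for that ORF).
    """
    rows = []
    for row in orf_table.itertuples(index=False):
        vec = asite_vectors.get(row.transcript_id)
        if vec is None:
            rows.append((np.nan, np.nan, np.nan))
            continue
        m = CodonReadMatrix.from_profile(vec, row.start, row.end)
        if m.N == 0:
            rows.append((np.nan, np.nan, np.nan))
        else:
            rows.append(periodicity_features(m))
    return pd.DataFrame(rows, columns=["f1", "f2", "f3"], index=orf_table.index)


def call_orfs(
    transcripts: Sequence[Transcript],
    samples: Mapping[str, Sequence[ReadAlignment]],
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    min_reads: int = 10,
    n_pos: int = 1000,
    n_neg: int = 3000,
    cv_folds: int = 5,
    rng_seed: int = 0,
    p_threshold: float = 0.6,
    min_support: int = 2,
    rpkm_threshold: float = 0.2,
    min_inframe: float = 0.6,
    train_merged: bool = True,
) -> CallResult:
    """Run the full calling pipeline over one or more read samples."""
    index = TranscriptIndex(transcripts)
    rng = np.random.default_rng(rng_seed)

    offsets: dict[str, OffsetTable] = {}
    vectors: dict[str, dict[str, np.ndarray]] = {}
    library_sizes: dict[str, int] = {}
    for name, reads in samples.items():
        table = calibrate_offsets(reads, transcripts, min_inframe=min_inframe)
        offsets[name] = table
        stats: dict = {}
        asites = list(adjust_to_asite(reads, table, stats))
        vecs = asite_count_vectors(transcripts, asites, index)
        vectors[name] = vecs
        library_sizes[name] = int(sum(v.sum() for v in vecs.values()))
        log.info(
            "%s: %d A-site reads (%d dropped), selected lengths %s",
            name, stats["adjusted"], stats["dropped_unselected"],
            table.selected_lengths,
        )

    merged = {
        tx.transcript_id: sum(
            (vectors[s][tx.transcript_id] for s in samples), np.zeros(tx.length, dtype=np.int64)
        )
        for tx in transcripts
    }
    orfs = annotate_candidate_orfs(transcripts, merged, start_codons, min_reads)

    model_sources = {name: vectors[name] for name in samples}
    if train_merged and len(samples) > 1:
        model_sources["merged"] = merged
    models: dict[str, TranslationModel] = {}
    for name, vecs in model_sources.items():
        sample_table = annotate_candidate_orfs(transcripts, vecs, start_codons, min_reads)
        seed = int(rng.integers(0, 2**31 - 1))
        train = assemble_training_set(sample_table, n_pos, n_neg, rng_seed=seed)
        test = assemble_training_set(
            sample_table, n_pos, n_neg, rng_seed=seed + 1, exclude=train.index
        )
        models[name] = train_translation_model(
            train, test, cv_folds=cv_folds, rng_seed=seed, model_id=name
        )

    probs = pd.DataFrame(index=orfs.index)
    for name, model in models.items():
        vecs = model_sources[name]
        feats = features_for_orfs(orfs, vecs)
        p = np.full(len(orfs), np.nan)
        ok = feats.notna().all(axis=1)
        if ok.any():
            p[ok.to_numpy()] = model.predict(feats[ok])
        probs[f"P_{name}"] = p
        orfs[f"P_{name}"] = p

    orfs["n_support"] = (probs > p_threshold).sum(axis=1)
    orfs["consensus"] = consensus_calls(probs, min_support, p_threshold)

    span = (orfs["end"] - orfs["start"]).to_numpy()
    rpkm_cols = []
    for name in samples:
        vecs = vectors[name]
        lib = library_sizes[name]
        reads_in = np.array(
            [
                int(vecs[r.transcript_id][r.start : r.end].sum())
                for r in orfs.itertuples(index=False)
            ]
        ) if len(orfs) else np.array([], dtype=int)
        col = f"rpkm_{name}"
        orfs[col] = [
            orf_rpkm(int(n), int(l), lib) if lib > 0 else 0.0
            for n, l in zip(reads_in, span)
        ]
        rpkm_cols.append(col)
    orfs["expressed"] = [
        expression_filter(row, rpkm_threshold)
        for row in orfs[rpkm_cols].to_numpy()
    ] if len(orfs) else []
    orfs["called"] = orfs["consensus"] & orfs["expressed"]
    return CallResult(orfs, models, offsets, library_sizes)
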