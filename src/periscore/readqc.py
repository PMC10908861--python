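"""Metagene QC, 3-nt periodicity assessment and A-site offset calibration.

Ribosome-protected fragments of a given length carry their ribosome's
A-site at a roughly fixed distance downstream of the read 5' end.  This
module measures that geometry on annotated CDS anchors: it builds metagene
profiles of 5' ends around start/stop codons, scans candidate P-site
offsets for the one that maximises the in-frame fraction, and reports the
A-site offset (P-site anchor + 3 nt).  Fragment-length groups whose best
in-frame fraction does not exceed the selection threshold (default 0.6)
are excluded from downstream ORF calling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .annotation_io import AsitePosition, ReadAlignment, Transcript, TranscriptIndex

log = logging.getLogger(__name__)

DEFAULT_WINDOW = (-40, 61)
DEFAULT_CANDIDATES = (11, 18)  # inclusive P-site offset search range, nt
MIN_FRAGMENT_LENGTH = 20
MAX_FRAGMENT_LENGTH = 45


@dataclass
class MetageneProfile:
    """Read-5'-end counts relative to annotated start and stop codons."""

    fragment_length: int
    window: tuple[int, int]  # [lo, hi) relative positions
    counts: np.ndarray  # indexed by rel - lo, anchored at start codon 1st nt
    stop_counts: np.ndarray  # anchored at stop codon 1st nt

    def position_counts(self) -> Iterator[tuple[int, int]]:
        lo, _ = self.window
        for i, c in enumerate(self.counts):
            yield lo + i, int(c)


@dataclass
class OffsetEntry:
    fragment_length: int
    a_site_offset: int
    inframe_fraction: float
    selected: bool


class OffsetTable:
    """Per-fragment-length A-site offsets and in-frame fractions."""

    def __init__(self, entries: Iterable[OffsetEntry] = ()):
        self.entries: dict[int, OffsetEntry] = {e.fragment_length: e for e in entries}

    def __getitem__(self, fragment_length: int) -> OffsetEntry:
        return self.entries[fragment_length]

    def __contains__(self, fragment_length: int) -> bool:
        return fragment_length in self.entries

    def __iter__(self) -> Iterator[OffsetEntry]:
        return iter(self.entries.values())

    @property
    def selected_lengths(self) -> list[int]:
        return sorted(l for l, e in self.entries.items() if e.selected)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fragment_length\ta_site_offset\tinframe_fraction\tselected\n")
            for l in sorted(self.entries):
                e = self.entries[l]
                frac = "NA" if math.isnan(e.inframe_fraction) else f"{e.inframe_fraction:.6f}"
                fh.write(f"{l}\t{e.a_site_offset}\t{frac}\t{int(e.selected)}\n")

    @classmethod
    def from_tsv(cls, path) -> "OffsetTable":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("fragment_length")
            for line in fh:
                l, off, frac, sel = line.rstrip("\n").split("\t")
                entries.append(
                    OffsetEntry(
                        int(l),
                        int(off),
                        float("nan") if frac == "NA" else float(frac),
                        bool(int(sel)),
                    )
                )
        return cls(entries)


def _coding(transcripts: Sequence[Transcript]) -> list[Transcript]:
    anchors = [tx for tx in transcripts if tx.cds is not None]
    if not anchors:
        raise ValueError("no canonical anchors: no transcript has an annotated CDS")
    return anchors


def metagene_profile(
    reads: Iterable[ReadAlignment],
    transcripts: Sequence[Transcript],
    fragment_length: int,
    window: tuple[int, int] = DEFAULT_WINDOW,
    index: TranscriptIndex | None = None,
) -> MetageneProfile:
    """Aggregate 5' ends around start/stop codons of CDS-bearing transcripts."""
    anchors = _coding(transcripts)
    if index is None:
        index = TranscriptIndex(anchors)
    lo, hi = window
    if lo > -40 or hi < 61:
        raise ValueError("window must cover at least -40..+60 nt")
    counts = np.zeros(hi - lo, dtype=np.int64)
    stop_counts = np.zeros(hi - lo, dtype=np.int64)
    for r in reads:
        if r.fragment_length != fragment_length:
            continue
        for tx, tpos in index.hits(r.chrom, r.strand, r.five_prime_pos):
            if tx.cds is None:
                continue
            rel = tpos - tx.cds[0]
            if lo <= rel < hi:
                counts[rel - lo] += 1
            rel_stop = tpos - (tx.cds[1] - 3)
            if lo <= rel_stop < hi:
                stop_counts[rel_stop - lo] += 1
    return MetageneProfile(fragment_length, (lo, hi), counts, stop_counts)


def inframe_fraction(
    reads: Iterable[ReadAlignment],
    transcripts: Sequence[Transcript],
    fragment_length: int,
    offset: int,
    index: TranscriptIndex | None = None,
) -> float:
    """Fraction of offset-adjusted positions in CDS landing on codon position 1.

    Returns NaN when no adjusted position falls inside a canonical CDS
    (the group is then unselectable).
    """
    anchors = _coding(transcripts)
    if index is None:
        index = TranscriptIndex(anchors)
    in_frame = total = 0
    for r in reads:
        if r.fragment_length != fragment_length:
            continue
        for tx, tpos in index.hits(r.chrom, r.strand, r.five_prime_pos):
            if tx.cds is None:
                continue
            adj = tpos + offset
            cs, ce = tx.cds
            if cs <= adj < ce:
                total += 1
                if (adj - cs) % 3 == 0:
                    in_frame += 1
    if total == 0:
        return float("nan")
    return in_frame / total


def calibrate_offsets(
    reads: Iterable[ReadAlignment],
    transcripts: Sequence[Transcript],
    fragment_lengths: Sequence[int] | None = None,
    candidate_range: tuple[int, int] = DEFAULT_CANDIDATES,
    min_inframe: float = 0.6,
    min_fragment_length: int = MIN_FRAGMENT_LENGTH,
    max_fragment_length: int = MAX_FRAGMENT_LENGTH,
) -> OffsetTable:
    """Choose, per fragment length, the offset maximising the in-frame fraction.

    The P-site candidate search runs over ``candidate_range`` (inclusive);
    among equally good candidates the one closest to the dominant upstream
    metagene peak wins, remaining ties break to the smaller offset with a
    logged warning.  The reported A-site offset is the chosen P-site anchor
    + 3 nt; a group is ``selected`` when its in-frame fraction exceeds
    ``min_inframe`` (strict).
    """
    reads = [
        r
        for r in reads
        if min_fragment_length <= r.fragment_length <= max_fragment_length
    ]
    anchors = _coding(transcripts)
    index = TranscriptIndex(anchors)
    if fragment_lengths is None:
        fragment_lengths = sorted({r.fragment_length for r in reads})

    lo_c, hi_c = candidate_range
    entries = []
    for length in fragment_lengths:
        group = [r for r in reads if r.fragment_length == length]
        prof = metagene_profile(group, anchors, length, index=index)
        lo, _ = prof.window

        def upstream_count(offset: int) -> int:
            rel = -offset
            return int(prof.counts[rel - lo]) if lo <= rel < 0 else 0

        fracs = {
            c: inframe_fraction(group, anchors, length, c, index=index)
            for c in range(lo_c, hi_c + 1)
        }
        finite = {c: f for c, f in fracs.items() if not math.isnan(f)}
        if not finite:
            entries.append(OffsetEntry(length, 12 + 3, float("nan"), False))
            continue
        # candidates 3 nt apart probe the same frame and differ only by edge
        # noise, so pick the best frame class first, then anchor within it at
        # the dominant metagene peak (the P-site offset is the distance from
        # the 5' peak to the start codon)
        classes: dict[int, list[float]] = {}
        for c, f in finite.items():
            classes.setdefault(c % 3, []).append(f)
        means = {k: sum(v) / len(v) for k, v in classes.items()}
        best_mean = max(means.values())
        tied = sorted(k for k, v in means.items() if v >= best_mean - 1e-12)
        if len(tied) > 1:
            log.warning(
                "fragment length %d: in-frame tie between frame classes %s; "
                "taking the one with the smaller offsets",
                length, tied,
            )
        winners = sorted(c for c in finite if c % 3 == tied[0])
        # within the winning frame class, anchor on the dominant metagene
        # peak: initiation pausing puts the tallest upstream 5'-end pile-up
        # exactly one P-site offset before the start codon
        peak = max(upstream_count(c) for c in winners)
        anchored = [c for c in winners if upstream_count(c) == peak]
        if len(anchored) > 1:
            log.warning(
                "fragment length %d: metagene peak tie among offsets %s; "
                "taking smallest", length, anchored,
            )
        chosen = min(anchored)
        entries.append(
            OffsetEntry(length, chosen + 3, fracs[chosen], fracs[chosen] > min_inframe)
        )
    return OffsetTable(entries)


def adjust_to_asite(
    reads: Iterable[ReadAlignment],
    offsets: OffsetTable,
    stats: dict | None = None,
) -> Iterator[AsitePosition]:
    """Shift 5' ends to A-sites; reads of unselected lengths are dropped.

    The shift is applied in the 5'->3' direction of the read's strand:
    plus-strand positions move right, minus-strand positions move left.
    """
    if stats is None:
        stats = {}
    stats.setdefault("adjusted", 0)
    stats.setdefault("dropped_unselected", 0)
    for r in reads:
        entry = offsets.entries.get(r.fragment_length)
        if entry is None or not entry.selected:
            stats["dropped_unselected"] += 1
            continue
        off = entry.a_site_offset
        pos = r.five_prime_pos + off if r.strand == "+" else r.five_prime_pos - off
        stats["adjusted"] += 1
        yield AsitePosition(r.chrom, pos, r.strand)
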