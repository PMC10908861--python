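"""Gene models, genome sequences, read alignments and coordinate maps.

All coordinates are 0-based half-open internally; 1-based GTF/SAM input is
converted on read.  Transcript coordinates run 5'->3' along the mature
(spliced) transcript, so position 0 is the cap-proximal base regardless of
genomic strand.  The annotated CDS interval is stored in transcript
coordinates and *includes* the stop codon, so a CDS of ``3*(aa+1)+3`` nt
encodes ``aa`` residues plus the initiator Met.
"""

from __future__ import annotations

import bisect
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadAlignment:
    """A single aligned ribosome-protected fragment, reduced to its 5' end."""

    chrom: str
    five_prime_pos: int
    fragment_length: int
    strand: str

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")
        if self.five_prime_pos < 0:
            raise ValueError("five_prime_pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class AsitePosition:
    """A single-nucleotide, A-site-adjusted read position."""

    chrom: str
    pos: int
    strand: str


class Transcript:
    """A gene model: exon blocks on a chromosome plus optional CDS/sequence.

    Parameters
    ----------
    exons:
        Genomic intervals (0-based half-open), non-overlapping.  They are
        sorted by genomic start on construction; transcript coordinates are
        derived strand-aware, so for minus-strand models coordinate 0 maps
        to the genomically right-most exonic base.
    cds:
        Optional (start, end) in *transcript* coordinates, stop codon
        included; length must be a multiple of 3 and >= 6.
    """

    __slots__ = (
        "transcript_id",
        "gene_id",
        "biotype",
        "chrom",
        "strand",
        "exons",
        "cds",
        "sequence",
        "_starts",
        "_offsets",
    )

    def __init__(
        self,
        transcript_id: str,
        gene_id: str,
        biotype: str,
        chrom: str,
        strand: str,
        exons: Sequence[tuple[int, int]],
        cds: tuple[int, int] | None = None,
        sequence: str | None = None,
    ) -> None:
        if strand not in ("+", "-"):
            raise ValueError(f"bad strand {strand!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in exons))
        if not exons:
            raise ValueError(f"{transcript_id}: transcript needs >= 1 exon")
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"{transcript_id}: empty exon [{a},{b})")
        for (_, b), (a2, _) in zip(exons, exons[1:]):
            if a2 < b:
                raise ValueError(f"{transcript_id}: overlapping exons")
        self.transcript_id = transcript_id
        self.gene_id = gene_id
        self.biotype = biotype
        self.chrom = chrom
        self.strand = strand
        self.exons = exons
        # cumulative plus-strand offsets for the coordinate map
        self._starts = [a for a, _ in exons]
        offs, acc = [], 0
        for a, b in exons:
            offs.append(acc)
            acc += b - a
        self._offsets = offs
        if cds is not None:
            cds = (int(cds[0]), int(cds[1]))
            span = cds[1] - cds[0]
            if span < 6 or span % 3 != 0:
                raise ValueError(
                    f"{transcript_id}: CDS span {span} not a multiple of 3 >= 6"
                )
            if cds[0] < 0 or cds[1] > self.length:
                raise ValueError(f"{transcript_id}: CDS outside transcript")
        self.cds = cds
        if sequence is not None:
            sequence = sequence.upper()
            if len(sequence) != self.length:
                raise ValueError(
                    f"{transcript_id}: sequence length {len(sequence)} != "
                    f"exonic length {self.length}"
                )
            if set(sequence) - set("ACGTN"):
                raise ValueError(f"{transcript_id}: non-ACGTN characters")
        self.sequence = sequence

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    # ---- coordinate maps -------------------------------------------------

    def _plus_coord(self, gpos: int) -> int | None:
        i = bisect.bisect_right(self._starts, gpos) - 1
        if i < 0:
            return None
        a, b = self.exons[i]
        if gpos >= b:
            return None
        return self._offsets[i] + (gpos - a)

    def to_transcript(self, gpos: int) -> int | None:
        """Transcript coordinate of a genomic position, or None if intronic/outside."""
        t = self._plus_coord(gpos)
        if t is None:
            return None
        return t if self.strand == "+" else self.length - 1 - t

    def to_genome(self, tpos: int) -> int:
        """Genomic position of a transcript coordinate (inverse of to_transcript)."""
        if not 0 <= tpos < self.length:
            raise IndexError(f"transcript position {tpos} outside [0,{self.length})")
        p = tpos if self.strand == "+" else self.length - 1 - tpos
        i = bisect.bisect_right(self._offsets, p) - 1
        a, _ = self.exons[i]
        return a + (p - self._offsets[i])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Transcript({self.transcript_id}, {self.chrom}{self.strand}, "
            f"{len(self.exons)} exons, L={self.length}, cds={self.cds})"
        )


class TranscriptIndex:
    """Exonic genomic position -> (transcript, transcript coordinate) lookup."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts = list(transcripts)
        self._by_pos: dict[tuple[str, str, int], list[tuple[int, int]]] = {}
        for i, tx in enumerate(self.transcripts):
            for a, b in tx.exons:
                for g in range(a, b):
                    t = tx.to_transcript(g)
                    key = (tx.chrom, tx.strand, g)
                    self._by_pos.setdefault(key, []).append((i, t))

    def hits(self, chrom: str, strand: str, gpos: int) -> list[tuple[Transcript, int]]:
        out = self._by_pos.get((chrom, strand, gpos), ())
        return [(self.transcripts[i], t) for i, t in out]


class GenomeSequence:
    """Chromosome name -> nucleotide string, with strand-aware access."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or end < start:
            raise IndexError(
                f"interval [{start},{end}) outside {chrom} (length {len(seq)})"
            )
        sub = seq[start:end]
        return sub if strand == "+" else reverse_complement(sub)


def transcript_sequence(genome: GenomeSequence, tx: Transcript) -> str:
    """Spliced 5'->3' transcript sequence from the genome.

    Minus-strand exons are reverse-complemented and concatenated in
    transcript order (genomically right-most exon first).
    """
    parts = [genome.fetch(tx.chrom, a, b, "+") for a, b in tx.exons]
    if tx.strand == "+":
        return "".join(parts)
    return "".join(reverse_complement(p) for p in reversed(parts))


def attach_sequences(transcripts: Iterable[Transcript], genome: GenomeSequence) -> None:
    for tx in transcripts:
        tx.sequence = transcript_sequence(genome, tx)


# ---------------------------------------------------------------------------
# gene-model loading
# ---------------------------------------------------------------------------


def load_gene_models(path: str | os.PathLike, format: str = "gtf") -> list[Transcript]:
    """Load transcript models from GTF (Ensembl/GENCODE dialect) or genePred TSV.

    CDS intervals are converted to transcript coordinates (stop codon
    included); transcripts whose annotated CDS span is not a multiple of 3
    are excluded with a logged warning.
    """
    if format == "gtf":
        return _load_gtf(path)
    if format == "genepred":
        return _load_genepred(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _attr(feature, *names: str, default: str | None = None) -> str | None:
    for n in names:
        if n in feature.attributes:
            return feature.attributes[n][0]
    return default


def _load_gtf(path: str | os.PathLike) -> list[Transcript]:
    import gffutils

    text = Path(path).read_text()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # surface the offending line if gffutils names it
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    has_stop: set[str] = set()
    meta: dict[str, tuple[str, str, str, str]] = {}
    for feat in db.all_features():
        tid = _attr(feat, "transcript_id")
        if tid is None:
            continue
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            cds.setdefault(tid, []).append(iv)
            if feat.featuretype == "stop_codon":
                has_stop.add(tid)
        if tid not in meta:
            gid = _attr(feat, "gene_id", default=tid)
            bt = _attr(
                feat, "gene_biotype", "transcript_biotype", "gene_type",
                "transcript_type",
            )
            meta[tid] = (gid, bt, feat.seqid, feat.strand)

    out: list[Transcript] = []
    for tid, ex in sorted(exons.items()):
        gid, bt, chrom, strand = meta[tid]
        cds_tx = None
        if tid in cds:
            tx_tmp = Transcript(tid, gid, bt or "protein_coding", chrom, strand, ex)
            span = sum(b - a for a, b in cds[tid])
            if tid not in has_stop:
                # GENCODE-style CDS excludes the stop codon; extend by 3 nt
                # (transcript coords) when no stop_codon feature is present.
                span += 3
            if span % 3 != 0 or span < 6:
                log.warning(
                    "%s: CDS span %d not a multiple of 3 (>=6); transcript excluded",
                    tid, span,
                )
                continue
            tpos = [tx_tmp.to_transcript(g) for a, b in cds[tid] for g in (a, b - 1)]
            if any(t is None for t in tpos):
                log.warning("%s: CDS outside exons; transcript excluded", tid)
                continue
            lo = min(tpos)
            cds_tx = (lo, lo + span)
            if cds_tx[1] > tx_tmp.length:
                log.warning("%s: CDS (stop extended) exceeds transcript; excluded", tid)
                continue
        bt = bt or ("protein_coding" if cds_tx else "unknown")
        out.append(Transcript(tid, gid, bt, chrom, strand, ex, cds=cds_tx))
    return out


def _load_genepred(path: str | os.PathLike) -> list[Transcript]:
    """genePred-style TSV: name chrom strand txStart txEnd cdsStart cdsEnd
    exonCount exonStarts exonEnds [gene_id [biotype]].  cdsStart==cdsEnd
    means no CDS; cdsEnd includes the stop codon (UCSC convention)."""
    out: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: expected >=10 columns, got {len(f)}")
            name, chrom, strand = f[0], f[1], f[2]
            cds_s, cds_e = int(f[5]), int(f[6])
            starts = [int(x) for x in f[8].rstrip(",").split(",") if x]
            ends = [int(x) for x in f[9].rstrip(",").split(",") if x]
            if len(starts) != len(ends) or len(starts) != int(f[7]):
                raise ValueError(f"{path}:{lineno}: exon count mismatch")
            gid = f[10] if len(f) > 10 else name
            bt = f[11] if len(f) > 11 else None
            ex = list(zip(starts, ends))
            cds_tx = None
            if cds_e > cds_s:
                tx_tmp = Transcript(name, gid, bt or "protein_coding", chrom, strand, ex)
                t5 = tx_tmp.to_transcript(cds_s if strand == "+" else cds_e - 1)
                t3 = tx_tmp.to_transcript(cds_e - 1 if strand == "+" else cds_s)
                if t5 is None or t3 is None:
                    raise ValueError(f"{path}:{lineno}: CDS bound not exonic")
                span = t3 - t5 + 1
                if span % 3 != 0 or span < 6:
                    log.warning(
                        "%s: CDS span %d not a multiple of 3 (>=6); transcript excluded",
                        name, span,
                    )
                    continue
                cds_tx = (t5, t3 + 1)
            bt = bt or ("protein_coding" if cds_tx else "unknown")
            out.append(Transcript(name, gid, bt, chrom, strand, ex, cds=cds_tx))
    return out


def write_gtf(transcripts: Iterable[Transcript], path: str | os.PathLike) -> None:
    """Write models as Ensembl-dialect GTF (exon + CDS + stop_codon features)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_biotype "{tx.biotype}";'
            )

            def row(ftype: str, a: int, b: int) -> str:
                return (
                    f"{tx.chrom}\tperiscore\t{ftype}\t{a + 1}\t{b}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )

            for a, b in tx.exons:
                fh.write(row("exon", a, b))
            if tx.cds is not None:
                cs, ce = tx.cds
                # emit per-exon genomic CDS blocks, stop codon as its own feature
                for t0, t1, ftype in ((cs, ce - 3, "CDS"), (ce - 3, ce, "stop_codon")):
                    gs = sorted(tx.to_genome(t) for t in range(t0, t1))
                    a = gs[0]
                    prev = gs[0]
                    for g in gs[1:]:
                        if g != prev + 1:
                            fh.write(row(ftype, a, prev + 1))
                            a = g
                        prev = g
                    fh.write(row(ftype, a, prev + 1))


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# read loading
# ---------------------------------------------------------------------------


def load_reads(
    path: str | os.PathLike,
    format: str = "bed5p",
    stats: dict | None = None,
) -> Iterator[ReadAlignment]:
    """Stream read alignments reduced to biological 5' ends.

    ``sam``/``bam``: only primary, uniquely mapped records are admitted
    (secondary/supplementary/unmapped and NH>1 records are skipped and
    counted in ``stats``).  The 5' end is the alignment start for plus-strand
    reads and ``alignment end - 1`` for minus-strand reads.

    ``bed5p``: 4-column TSV (chrom, 0-based 5' position, fragment length,
    strand) — the pre-reduced dialect the synthetic module emits.
    """
    if stats is None:
        stats = {}
    stats.setdefault("kept", 0)
    stats.setdefault("skipped_secondary", 0)
    stats.setdefault("skipped_multimapped", 0)
    stats.setdefault("skipped_unmapped", 0)

    if format in ("sam", "bam"):
        import pysam

        mode = "rb" if format == "bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    stats["skipped_unmapped"] += 1
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    stats["skipped_secondary"] += 1
                    continue
                if rec.has_tag("NH") and rec.get_tag("NH") > 1:
                    stats["skipped_multimapped"] += 1
                    continue
                length = rec.query_length or rec.infer_query_length()
                if rec.is_reverse:
                    pos, strand = rec.reference_end - 1, "-"
                else:
                    pos, strand = rec.reference_start, "+"
                stats["kept"] += 1
                yield ReadAlignment(rec.reference_name, pos, length, strand)
    elif format == "bed5p":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                stats["kept"] += 1
                yield ReadAlignment(f[0], int(f[1]), int(f[2]), f[3])
    else:
        raise ValueError(f"unknown read format {format!r}")


def write_reads_bed5p(reads: Iterable[ReadAlignment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.five_prime_pos}\t{r.fragment_length}\t{r.strand}\n")
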