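# Methods

This note documents the models implemented in `periscore`, the choices made
where the procedure was genuinely open, what the synthetic benchmark does
and does not emulate, and the problem sizes the shipped tests use.

## Read QC and A-site calibration (`readqc`)

Reads are grouped by fragment length (default admissible range 20–45 nt;
outside lengths are ignored). For each group a metagene profile of read 5′
ends is accumulated around annotated start and stop codons (window −40..+60
nt), and candidate P-site offsets in 11–18 nt are scanned. The in-frame
fraction at offset *c* is the fraction of (5′ + *c*) positions inside
canonical CDS that land on the first nucleotide of a codon.

Offsets 3 nt apart probe the same reading frame and differ only by edge
effects, so the scan first picks the frame class (offset mod 3) with the
best mean in-frame fraction, then anchors within the class at the dominant
upstream metagene peak: initiation-paused ribosomes pile 5′ ends exactly one
P-site offset before the start codon, which is the classic −12/−13 peak.
The reported A-site offset is the chosen P-site anchor + 3 nt. Exact ties
(between frame classes, or between equal peaks) break deterministically to
the smaller offset with a logged warning. A group is selected for ORF
calling only when its in-frame fraction exceeds `min_inframe` (default 0.6,
strict); groups with no CDS-overlapping reads are unselectable (NaN).

The in-frame fraction used for selection is the one at the optimal offset;
whether selection should instead precede offset optimisation is
underdetermined, and this order is the stable choice.

## Candidate ORFs and periodicity features (`orf_caller`)

Candidates are every (start codon, next in-frame stop) pair in all three
frames of a transcript; nested starts each open their own ORF, ORFs without
a downstream in-frame stop are dropped, and start/stop codons containing N
are skipped. Default start codons are {ATG, CTG, GTG, TTG, ATC} (NUG/AUC);
an ATG-only mode exists because the stability model is defined for
AUG-initiated ORFs. The ORF span includes the stop codon; peptide length in
aa is span/3 − 1 (the start codon encodes the first residue, so a 25-aa
peptide like RPL41 spans 78 nt). The read filter is strict: total
A-site-adjusted reads in the ORF must exceed `min_reads` (default 10).

The codon read matrix covers codons 1..L *excluding the start codon* and
including the stop codon row (L = span/3 − 1). f1 and f2 are as defined in
the README. PME details:

- Per-codon totals (n_i1 + n_i2 + n_i3) are used by default; an
  `inframe_only` flag restricts to first-nucleotide counts.
- Region length is 1 codon when N > L, else ⌊L/N⌋; the final partial region
  is retained so no codon is discarded.
- The entropy is computed with 0·log 0 = 0, and the reference maximum is the
  entropy of the most even integer allocation of N reads over the m regions
  (region counts differing by at most 1); a brute-force enumeration over all
  integer compositions confirms this allocation is the entropy maximiser on
  every tested instance. When m = 1 (possible only at N = 1) the ratio is
  defined as 1. f3 is clipped to [0,1] against floating-point spill.

ORF-type labels partition candidates deterministically. On noncoding
biotypes the biotype wins (lncRNA-ORF, pseudogene-ORF). On coding
transcripts, with CDS [cs, ce) in transcript coordinates: exact match →
canonical; same stop and same frame but different start →
truncated/extended-canonical; end ≤ cs → uORF; start ≥ ce → dORF; start <
cs with overlap → ouORF; contained with frame shift → iORF; otherwise →
odORF. Boundary conventions (e.g. an off-frame ORF spanning the whole CDS
counts as ouORF) are explicit in `classify_orf_type`; edge cases at
category borders are a known ambiguity of the scheme.

### Training and calling

Positives are canonical ORFs; the negative pool is internal off-frame ORFs
(iORFs on coding transcripts) plus any candidate with f3 < 0.1 (footprint
pile-ups typical of non-ribosomal RNA–protein complexes). Default draw is
1000 positives + 3000 negatives without replacement, with a logged
shortfall when pools are smaller; a disjoint equally-sized draw serves as
the held-out test set. One model is trained per read sample plus one on the
merged reads.

The logistic fit uses a mild L2 penalty (scikit-learn `C=10`). On clean
data the three features separate the classes completely and the unpenalized
maximum-likelihood estimate diverges with arbitrary coefficient signs; the
mild penalty keeps the fit defined and the coefficients interpretable while
leaving predicted probabilities decisive (canonical ORFs score ≈ 1). The
stability model (below) is fit unpenalized, matching a plain-GLM protocol,
because curated stable/undetectable classes overlap.

Consensus requires ≥ `min_support` (default 2) models with P strictly >
0.6. Expression requires RPKM strictly > 0.2 in ≥ 1 sample, with RPKM =
reads/(length/1000)/(library/10⁶) computed from A-site-adjusted reads in
the ORF over the sample's adjusted-read total. This direct RPKM replaces
isoform-level EM quantification; on shared exons it attributes reads to
every overlapping isoform, which slightly over-counts relative to an EM
split but needs no extra machinery and uses exactly the reads the caller
already placed.

## ORF-length null and FDR (`length_fdr`)

Pseudo-transcripts are mononucleotide permutations of the transcript
sequence and/or uniformly sampled N-free genomic windows of the same length
(1000 per source by default; a dinucleotide-preserving shuffle is available
behind a flag). All AUG→stop ORFs are enumerated per pseudo-transcript
(nested ATGs each count; no other exclusions) and pooled across sources.
FDR(observed) = #{null lengths strictly > observed}/n, so ties do not
inflate the count; the expected length at level α is the smallest integer
length whose FDR is ≤ α. When FDR = 0 the downstream t1 feature floors it
at 1/(n+1), the add-one pseudocount on the empirical tail.

For i.i.d. sequences the null length law converges to a geometric
distribution with per-codon stop probability p of the composition; the
tests verify KS distance < 0.02 at ≥ 10⁵ pooled ORFs on 10-kb sequences.
On ~1-kb transcripts the null is systematically a few percent *shorter*
than the geometric limit because each start's downstream window is
truncated at the transcript end — which is also why expected length grows
with transcript length. `geometric_expected_length(alpha, p, max_codons)`
evaluates the finite-length closed form (windowed geometric tail); at 1 kb
it predicts 54 aa (5% FDR) and 70 aa (2% FDR) for GC ≈ 47%, matching both
the simulation here and the ~55/73 aa scale reported for real ~1-kb
transcripts.

## Peptide stability model (`pepscore`)

Features: t1 = −log₁₀(max(FDR, 1/(n+1))); t2 = 1 iff a Pfam or TMHMM hit
exists in a user-supplied domain table (IDs absent from the table count as
0 with a logged notice — domain search is consumed, never executed); t3 =
log₁₀(|Σfᵢ| + 1)·sign(Σfᵢ) over per-codon conservation scores supplied as
a table (sign(0) = 0; the explicit signed-log formula is used throughout).

Training draws 200 examples (stratified by class so every CV fold sees both
classes; an unstratified mode exists) and a disjoint 100 for the held-out
AUROC, from a labelled pool that may be larger — mirroring a curated
collection where only part of the labelled set enters each split. The
scorer refuses non-AUG rows unless forced, and `high_pepscore` is strict
(> 0.6; a score of exactly 0.6 is not flagged).

Sequence annotations: the Kozak score sums seven positional rules (G at −6:
+3; C at −5, −4: +1; G/A at −3: +3; C at −2, −1: +1; G at +1: +3; range
0–13); with < 6 nt of 5′ context only the available positions are scored
(missing positions contribute 0 rather than being imputed). The
optimal-codon fraction counts membership in the 17-codon high-usage list
over non-stop codons, start included. Amino-acid category fractions are
evaluated per category over overlapping sets (C, for example, is both polar
and hydrophilic), so they need not sum to 1. Tau = Σ(1 − xᵢ/max x)/(n − 1)
requires ≥ 2 tissues and is NaN for an all-zero profile.

## Synthetic benchmark (`synthetic`)

The generator plants ground truth at every level. Transcripts have
5′UTR/CDS/3′UTR architecture (UTRs 100–180 nt, CDS 100–200 aa by default)
with uORFs (10–30 aa) and dORFs (8–20 aa) planted in the UTRs, a fraction
of lncRNA transcripts carrying their own ORFs, and two-exon/minus-strand
models to exercise the coordinate maps. Each planted ncORF is translated
with probability 0.6, a localized artifact with probability 0.15 (all reads
on ≤ 2 adjacent positions within one codon, driving PME < 0.1), else a
frame-uniform noise locus.

Reads at translated loci draw codons from a Dirichlet-multinomial
(concentration 5 over the ORF body — mild coverage unevenness), codon
positions from the in-frame bias (0.75, 0.15, 0.10), and 8% of reads are
placed at the first body codon to emulate initiation pausing (the metagene
anchor real offset calibration relies on). The default depth is 60 reads
per translated ORF with ~15 frame-uniform background reads per transcript.
5′ ends are back-computed from A-sites through per-length offsets
({28:15, 29:15, 30:16} by default) so the QC stage must re-derive them.
The 0.75 in-frame bias leaves clear headroom over the 0.6 selection
threshold while keeping features noisy enough that classifier evaluation is
non-trivial at the default depth.

What the generator does **not** emulate: RNase digestion and ligation
sequence biases, UMI duplication structure, isoform mixtures sharing exons,
uneven codon-level dwell times beyond the Dirichlet dispersion, and
multi-mapping reads. Passing benchmarks therefore demonstrates correctness
of the statistical machinery under its stated model, not robustness to
every artefact of real libraries.

The PepScore feature generator draws class-conditional (t1, t2, t3):
negatives t1 ~ |N(0.7, 1.2)|, domain rate 0.15, t3 ~ N(−0.5, 1.5);
positives shift t1 by +2, multiply the domain odds by 5, and shift t3 by
+1 — stable peptides have more significant length FDRs, more domains and
higher conservation, with enough class overlap that maximum likelihood is
well behaved. A separate generator draws labels from a known logistic model
for coefficient-recovery tests.

## Problem sizes and determinism

The shipped test suite runs the full pipeline on 200 transcripts × 2
samples (training 80 + 240 per model with disjoint test draws), builds the
1-kb calibration null from 2,000 pseudo-transcripts (~31,000 pooled null
ORFs) and the geometric-limit null from 650 × 10-kb sequences (~10⁵ ORFs);
these sizes give stable statistics while keeping the whole suite around
half a minute. All randomness flows through explicit numpy Generators
seeded per test; `scripts/acceptance.py` derives everything from its
`--seed`.

## Known limitations

- Reads are assigned per-transcript by exact exonic 5′-end position;
  reads whose 5′ end is intronic for a given isoform are dropped for that
  isoform (junction-spanning ends are not projected).
- The direct RPKM over-counts on exons shared between isoforms (no EM
  reassignment).
- ouORF/odORF boundary conventions at category edges are explicit but not
  the only defensible partition.
- Domain presence and conservation are consumed as tables; running Pfam,
  TMHMM or PhyloCSF is out of scope, as are mass-spectrometry validation
  and cross-species BLASTP conservation calls.
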