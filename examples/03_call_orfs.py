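"""Call translated ORFs end to end on two simulated samples.

Candidates (NUG/AUC start to in-frame stop, >10 A-site reads) are scored by
three periodicity features -- f1 (in-frame read fraction), f2 (fraction of
codons whose first nucleotide wins), f3 (PME read-uniformity entropy ratio)
-- with one logistic model per sample plus a merged-reads model.  An ORF is
called when >= 2 models give P > 0.6 and RPKM > 0.2 somewhere.
"""

import warnings

import numpy as np

from periscore import pipeline, synthetic

warnings.filterwarnings("ignore")

spec = synthetic.SimulationSpec(n_transcripts=100)
rng = np.random.default_rng(0)
transcripts, genome, truth = synthetic.simulate_transcriptome(spec, rng)
samples = {
    "cellA": synthetic.simulate_ribo_reads(transcripts, truth, spec.reads, rng),
    "cellB": synthetic.simulate_ribo_reads(transcripts, truth, spec.reads, rng),
}

result = pipeline.call_orfs(transcripts, samples, n_pos=60, n_neg=180, rng_seed=0)
table = result.orf_table

print("candidate ORFs by type (✓ = consensus-called):")
for orf_type, group in table.groupby("orf_type"):
    print(f"  {orf_type:<30} {len(group):>5} candidates, {group['called'].sum():>4} called")

for name, model in result.models.items():
    coefs = ", ".join(f"{k}={v:.1f}" for k, v in model.coef.items())
    print(f"model {name:<7} held-out AUROC={model.test_auroc:.3f}  ({coefs})")

canon = table[table["orf_type"] == "canonical"]
print(f"\ncanonical sensitivity: {canon['called'].mean():.3f} over {len(canon)} ORFs")
# High AUROC and positive coefficients on all three features mean periodic
# (translated) loci are cleanly separated from off-frame/localized signal.
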