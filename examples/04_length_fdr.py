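"""ORF-length FDR: is an observed ORF longer than chance allows?

1000 pseudo-transcripts are generated by shuffling the transcript sequence
(and optionally sampling genome windows of the same length); every AUG->stop
ORF in them forms the null.  FDR = fraction of null ORFs strictly longer
than the observed one.
"""

import numpy as np

from periscore import length_fdr, synthetic

rng = np.random.default_rng(0)
composition = (0.265, 0.235, 0.235, 0.265)  # A,C,G,T -- GC ~= 47%

# a 1-kb "transcript" carrying a 60-aa ORF
tx_seq = synthetic.simulate_genome(1000, composition, rng)
null = length_fdr.build_null(1000, tx_sequence=tx_seq, n_pseudo=1000, rng=rng)

print(f"null: {null.n} pseudo-ORFs from 1000 shuffles of a 1-kb transcript")
for observed in (20, 40, 60, 80):
    fdr = length_fdr.orf_length_fdr(null, observed)
    t1 = -np.log10(max(fdr, 1 / (null.n + 1)))
    print(f"  observed {observed:>3} aa -> FDR {fdr:.4f}  (t1 = {t1:.2f})")

for alpha in (0.05, 0.02):
    print(f"expected length at {alpha:.0%} FDR: "
          f"{length_fdr.expected_length_at_fdr(null, alpha)} aa")
# An ORF of 60+ aa on a 1-kb transcript is already longer than ~95% of what
# random sequence produces; the t1 feature feeds this into PepScore.
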