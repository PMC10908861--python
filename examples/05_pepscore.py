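"""Train PepScore and score peptides for stable expression.

Features per AUG-initiated ORF: t1 = -log10(length FDR), t2 = Pfam/TMHMM
domain indicator, t3 = signed-log PhyloCSF conservation sum.  Scores > 0.6
flag peptides likely to be stably expressed.
"""

import warnings

import numpy as np
import pandas as pd

from periscore import pepscore, synthetic

warnings.filterwarnings("ignore")

# class-conditional draws standing in for a curated stable/undetectable set
labelled = synthetic.simulate_pepscore_features(150, 150, rng=1)

model = pepscore.train_pepscore(labelled, n_train=200, n_test=100, rng_seed=1)
print(f"train n={model.n_train}, test n={model.n_test}")
print(f"cross-validated AUROC: {model.cv_auroc:.3f}")
print(f"held-out AUROC:        {model.test_auroc:.3f}")
print("coefficients:", {k: round(v, 2) for k, v in model.coef.items()})

candidates = pd.DataFrame(
    {
        "orf": ["long_conserved_domain", "long_only", "short_unconserved"],
        "t1": [pepscore.feature_t1(0.001, 1000),  # FDR 0.1%
               pepscore.feature_t1(0.02, 1000),
               pepscore.feature_t1(0.6, 1000)],
        "t2": [pepscore.feature_t2({"long_conserved_domain": {"PF00001"}},
                                   "long_conserved_domain"), 0, 0],
        "t3": [pepscore.feature_t3([2.0] * 50),  # positive PhyloCSF sum
               pepscore.feature_t3([0.0] * 50),
               pepscore.feature_t3([-1.0] * 30)],
    }
)
scored = pepscore.score_peptides(model, candidates)
print("\n", scored[["orf", "t1", "t2", "t3", "pepscore", "high_pepscore"]]
      .to_string(index=False))
# A significant length FDR is the dominant signal; domains and conservation
# push borderline peptides over the 0.6 stability threshold.
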