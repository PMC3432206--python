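"""Stage 1: simulate the prospective cohort and draw the study sample.

A 20,000-subject cohort over 2,000 SNPs with 10 causal variants under a
prospective logistic disease model, sampled down to a 700-case/750-control
retrospective study and split into training (476/487) and test sets.
Writes a cohort/sample summary to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from snprisk.pipeline import default_config, prepare_data

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=str, default="results")
args = ap.parse_args()

config = default_config(master_seed=args.seed)
cohort, train, test = prepare_data(config)

sim = config.simulation
rows = [
    ("n_snps", sim.n_snps),
    ("cohort_size", sim.cohort_size),
    ("n_causal_snps", len(sim.causal_effects)),
    ("cohort_prevalence", round(float(cohort.phenotype.mean()), 4)),
    ("sampled_cases", int(train.phenotype.sum() + test.phenotype.sum())),
    ("sampled_controls", int((train.phenotype == 0).sum() + (test.phenotype == 0).sum())),
    ("train_cases", int(train.phenotype.sum())),
    ("train_controls", int((train.phenotype == 0).sum())),
    ("test_cases", int(test.phenotype.sum())),
    ("test_controls", int((test.phenotype == 0).sum())),
    ("median_maf", round(float(np.median(np.minimum(
        cohort.genotypes.mean(0) / 2, 1 - cohort.genotypes.mean(0) / 2))), 4)),
]
summary = pd.DataFrame(rows, columns=["quantity", "value"])

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
summary.to_csv(out / "cohort_summary.csv", index=False)
print(summary.to_string(index=False))
print(f"\nWrote {out / 'cohort_summary.csv'}")
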