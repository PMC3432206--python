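"""Stage 3: the importance cascade and risk-rule construction.

Runs the 50% backstep elimination over the QC'd training SNPs, picks the
SNP sets nearest the configured target sizes, and fits every rule (allele
count, logOR, logistic regression on the smallest set, lasso, forests in
both modes) with Youden thresholds chosen on training data.  Writes the
fitted-rule summary to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from snprisk.pipeline import construct_rules, default_config, prepare_data

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=str, default="results")
args = ap.parse_args()

config = default_config(master_seed=args.seed)
_, train, _ = prepare_data(config)
train_qc, assoc, removal_log, snp_sets, models, skips = construct_rules(train, config)

print("cascade set sizes:", sorted(snp_sets, reverse=True))
rows = []
for (method, size), m in sorted(models.items()):
    rows.append(
        {
            "method": method,
            "set_size": size,
            "threshold": np.nan if m.threshold is None else round(m.threshold, 4),
            "youden_j_train": round(m.extra.get("youden_j_train", np.nan), 4)
            if m.extra.get("youden_j_train") is not None else np.nan,
            "n_nonzero_weights": np.nan if m.weights is None
            else int(np.count_nonzero(m.weights)),
            "lasso_penalty": round(m.extra["penalty"], 6)
            if "penalty" in m.extra else np.nan,
        }
    )
rules = pd.DataFrame(rows)
print(rules.to_string(index=False))
if skips:
    print("\nskipped combinations:")
    print(pd.DataFrame(skips).to_string(index=False))

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)
rules.to_csv(out / "rules.csv", index=False, float_format="%.6g")
print(f"\nWrote {out / 'rules.csv'}")
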