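"""Paired statistical comparison of the ensemble strategies.

DeLong on the rankable strategy pair (weighted sum vs threshold) and McNemar
on accuracy/sensitivity/specificity for every strategy pair, all on paired
predictions from the same studies. Output: results/comparisons.csv.
"""

import argparse
from pathlib import Path

from cxrtriage import RunConfig, read_score_table, run_validation

parser = argparse.ArgumentParser()
parser.add_argument("--input", type=Path, default=Path("results/synthetic_cohort.csv"))
parser.add_argument("--out", type=Path, default=Path("results/comparisons.csv"))
parser.add_argument("--holm", action="store_true", help="Holm-adjust p-values")
args = parser.parse_args()

cohort = read_score_table(args.input)
report = run_validation(cohort, RunConfig(holm=args.holm))
args.out.parent.mkdir(parents=True, exist_ok=True)
report.comparisons.to_csv(args.out, index=False)

print("paired comparisons (alpha = 0.05):")
for _, row in report.comparisons.iterrows():
    p = "undefined" if row["p_value"] is None else f"{row['p_value']:.4g}"
    flag = "*" if row["significant"] else " "
    print(f"  {row['comparison']:<32s} {row['metric']:<12s} {row['test']:<8s} p={p} {flag}")
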