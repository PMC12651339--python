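"""Stage 2: the four study-level ensemble strategies.

Runs the full two-stage pipeline on the cohort, writes the per-strategy
performance table (Wilson CIs, AUROC for the rankable strategies), the
per-study decisions with audit evidence, and the false-negative rescue
crosstab under results/.
"""

import argparse
from pathlib import Path

from cxrtriage import RunConfig, read_score_table, run_validation

parser = argparse.ArgumentParser()
parser.add_argument("--input", type=Path, default=Path("results/synthetic_cohort.csv"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = read_score_table(args.input)
report = run_validation(cohort, RunConfig())
report.write(args.out_dir)

import pandas as pd

decisions = pd.DataFrame(
    {"study_id": cohort.study_ids}
    | {s: v for s, v in report.decisions.items()}
)
decisions.to_csv(args.out_dir / "decisions.csv", index=False)

print(f"per-strategy performance on {cohort.n_studies} studies:")
for _, row in report.per_strategy.iterrows():
    auroc = f"{row['auroc']:.3f}" if pd.notna(row["auroc"]) else "N/A"
    print(
        f"  {row['name']:<13s} acc={row['acc']:.3f} "
        f"({row['acc_lo']:.3f}-{row['acc_hi']:.3f}) sens={row['sens']:.3f} "
        f"spec={row['spec']:.3f} AUROC={auroc}"
    )
print("\nfalse-negative rescue crosstab:")
print(report.crosstab.to_string(index=False))
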