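"""Generate the default synthetic validation cohort and write it to disk.

Emulates the enriched external-validation cohort: 1045 studies (477
abnormal, 568 normal), seven pathology channels with published positive-case
counts, binormal classifier scores matched to the published per-channel
AUROCs. Output: results/synthetic_cohort.csv.
"""

import argparse
from pathlib import Path

from cxrtriage import CohortSpec, generate_cohort, write_score_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/synthetic_cohort.csv"))
args = parser.parse_args()

cohort = generate_cohort(CohortSpec(seed=args.seed))
args.out.parent.mkdir(parents=True, exist_ok=True)
write_score_table(cohort, args.out)

n_abn, n_norm, _ = cohort.label_counts("yesfinding")
print(f"wrote {cohort.n_studies} studies to {args.out}")
print(f"composition: {n_abn} abnormal / {n_norm} normal")
for ch in cohort.channels[1:]:
    print(f"  {ch}: {cohort.label_counts(ch)[0]} positive")
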