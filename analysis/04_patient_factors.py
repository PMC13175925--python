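#!/usr/bin/env python
"""Correlate per-case lung volume/density factors with CTVI accuracy.

Computes, for each phantom case, whole-lung volumes in both phases,
absolute and percentage volume change, mean HU, percentage of air
trapping (exhale voxels < -850 HU) and the density coefficient of
variation, then the Pearson correlation (with Fisher-z 95% CI) of each
factor against per-case Spearman accuracy of CTVI_Jac and CTVI_HU from
the baseline run (analysis/02).  Writes results/patient_factors.csv and
results/factor_accuracy_table.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ctvi_lab import compute_factors, default_cohort, factor_accuracy_table, segment_lungs
from ctvi_lab.patient_factors import factors_frame

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=8)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    metrics_path = ROOT / "results" / "baseline_metrics.csv"
    if not metrics_path.exists():
        raise SystemExit("run analysis/02_baseline_validation.py first (same --n/--seed)")
    metrics = pd.read_csv(metrics_path)
    if len(metrics) != args.n:
        raise SystemExit("baseline_metrics.csv does not match --n; rerun analysis/02")

    factors, kept_ids = [], []
    for cid, case in enumerate(default_cohort(args.n, base_seed=args.seed)):
        mask_ex = segment_lungs(case.exhale_ct, -250.0)
        mask_in = segment_lungs(case.inhale_ct, -250.0)
        if mask_ex.n_true == 0 or mask_in.n_true == 0:
            # mirror clinical practice: cases with failed masks are excluded
            print(f"case {cid}: segmentation failed in one phase -> excluded")
            continue
        factors.append(compute_factors(case.inhale_ct, case.exhale_ct, mask_in, mask_ex))
        kept_ids.append(cid)
    if len(factors) < 4:
        raise SystemExit("fewer than 4 cases with valid masks; enlarge the cohort")
    kept = metrics[metrics.case_id.isin(kept_ids)]

    out = ROOT / "results"
    frame = factors_frame(factors, case_ids=kept_ids)
    frame.to_csv(out / "patient_factors.csv", index=False)
    print(frame.round(3).to_string(index=False))

    table = factor_accuracy_table(
        factors, {"Jac": kept.r_s_jac.to_numpy(), "HU": kept.r_s_hu.to_numpy()}
    )
    table.to_csv(out / "factor_accuracy_table.csv", index=False)
    print("\nPearson correlation of factors with accuracy (r [95% CI], p):")
    for _, row in table.iterrows():
        print(f"  {row.factor:<42s} {row.method:<4s} "
              f"{row.r:+.2f} [{row.ci_lo:+.2f}, {row.ci_hi:+.2f}]  p={row.p:.3f}")


if __name__ == "__main__":
    main()
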