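#!/usr/bin/env python
"""Evaluate the self-correlation quality metric against true accuracy.

The Spearman correlation between paired CTVI_Jac and CTVI_HU needs no
ground truth.  Using the lambda-sweep cells from analysis/03, this
script correlates it (Pearson, per method) with the true accuracy r_S
against the reference across all (case, lambda) cells, and reports the
lambda maximizing the cohort-mean self-correlation.  Writes
results/self_correlation_vs_accuracy.csv.
"""

from pathlib import Path

import pandas as pd

from ctvi_lab import pearson_ci

ROOT = Path(__file__).resolve().parents[1]


def main():
    cells_path = ROOT / "results" / "sweeps" / "dir_lambda_cells.csv"
    if not cells_path.exists():
        raise SystemExit("run analysis/03_parameter_sweeps.py first")
    cells = pd.read_csv(cells_path)
    ok = cells[~cells.excluded]

    rows = []
    for method in ("r_s_jac", "r_s_hu"):
        rep = pearson_ci(ok.self_corr.to_numpy(), ok[method].to_numpy())
        rows.append({"method": method, "r_p": rep.r, "ci_lo": rep.ci95[0],
                     "ci_hi": rep.ci95[1], "p": rep.p, "n": rep.n})
        print(f"self-correlation vs {method}: r_P = {rep.r:.2f} "
              f"[{rep.ci95[0]:.2f}, {rep.ci95[1]:.2f}], p = {rep.p:.2g}, n = {rep.n}")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "self_correlation_vs_accuracy.csv", index=False)

    means = ok.groupby("value")["self_corr"].mean()
    lam_star = means.index[means.argmax()]
    print(f"lambda maximizing mean self-correlation: {lam_star:g}")


if __name__ == "__main__":
    main()
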