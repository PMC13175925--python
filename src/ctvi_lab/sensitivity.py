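"""One-at-a-time parameter sweeps, robust-range identification, and
self-correlation-based lambda optimization.

Each sweep varies a single parameter from the baseline (lung segmentation
threshold -250 HU, DIR regularization lambda = 1, median-filter diameter
3 voxels) while holding the others fixed:

* threshold sweep: -600 ... -150 HU in 50 HU steps (10 masks), re-segment
  and re-register per value;
* lambda sweep: 18 geometrically spaced values from 0.05 to 100,
  re-register per value;
* filter sweep: diameters {0, 3, 5, 7, 9}, reusing the baseline
  registration and re-smoothing only (observable-equivalent shortcut).

Cells whose registration produced negative Jacobian values in the lungs
are excluded from cohort means (folding exclusion rule).  A robust range
is the maximal contiguous run of sweep values, containing the argmax,
whose mean r_S stays within 10% of the highest observed mean with no
folding in any included case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .phantom import PhantomCase
from .pipeline import CaseResult, run_phantom_case

__all__ = [
    "BASELINE",
    "SweepSpec",
    "SweepResult",
    "RobustRange",
    "default_sweeps",
    "run_sweep",
    "robust_range",
    "optimize_lambda_by_self_correlation",
]

BASELINE = {"lung_threshold_hu": -250.0, "dir_lambda": 1.0, "filter_diameter_vox": 3}

ParameterName = Literal["lung_threshold_hu", "dir_lambda", "filter_diameter_vox"]


@dataclass(frozen=True)
class SweepSpec:
    """One parameter to vary and the ordered grid of values."""

    parameter: ParameterName
    values: tuple
    baseline: dict = field(default_factory=lambda: dict(BASELINE))

    def __post_init__(self):
        if self.parameter not in BASELINE:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not self.values:
            raise ValueError("sweep needs at least one value")


def default_sweeps() -> list[SweepSpec]:
    """The three standard sweeps: threshold, lambda, filter diameter."""
    thresholds = tuple(np.arange(-600.0, -149.0, 50.0))  # 10 values
    lambdas = tuple(np.geomspace(0.05, 100.0, 18))
    diameters = (0, 3, 5, 7, 9)
    return [
        SweepSpec("lung_threshold_hu", thresholds),
        SweepSpec("dir_lambda", lambdas),
        SweepSpec("filter_diameter_vox", diameters),
    ]


@dataclass
class SweepResult:
    """Per-(case, value) metrics plus folding-aware per-value means."""

    spec: SweepSpec
    table: pd.DataFrame  # case_id, value, r_s_jac, r_s_hu, self_corr, pct_neg_jac, mse_after, excluded

    def means(self) -> pd.DataFrame:
        """Per-value means over non-excluded cases (the exclusion rule)."""
        ok = self.table[~self.table["excluded"]]
        g = ok.groupby("value", sort=False)[["r_s_jac", "r_s_hu", "self_corr", "mse_after"]].mean()
        out = g.reindex([_scalar(v) for v in self.spec.values])
        out["n_included"] = ok.groupby("value", sort=False).size().reindex(out.index).fillna(0).astype(int)
        out["any_neg_jac"] = (
            self.table.groupby("value", sort=False)["pct_neg_jac"].max().reindex(out.index) > 0
        )
        return out

    def heatmap_matrix(self, metric: str = "r_s_jac") -> pd.DataFrame:
        """Cases as rows, parameter values as columns (heat-map layout)."""
        return self.table.pivot(index="case_id", columns="value", values=metric)


@dataclass(frozen=True)
class RobustRange:
    """Maximal contiguous run around the argmax meeting the robustness criterion."""

    parameter: str
    method: str
    lo: float | None
    hi: float | None
    max_mean_r: float
    tolerance: float
    empty: bool = False

    @property
    def values(self):
        return (self.lo, self.hi)


def _scalar(v):
    return float(v) if not isinstance(v, (int, np.integer)) else int(v)


def run_sweep(cases: Sequence[PhantomCase], spec: SweepSpec, **pipeline_kwargs) -> SweepResult:
    """Run the pipeline over every (case, value) cell of one sweep.

    Filter sweeps reuse each case's baseline registration and only
    re-smooth; threshold and lambda sweeps re-register per value.
    """
    if not cases:
        raise ValueError("need at least one case")
    base = dict(spec.baseline)
    base.update(pipeline_kwargs)
    rows = []
    for ci, case in enumerate(cases):
        if spec.parameter == "filter_diameter_vox":
            pairs = []
            baseline_reg = None
            for v in spec.values:
                kwargs = {**base, "filter_diameter_vox": int(v)}
                if baseline_reg is not None:
                    kwargs["registration"] = baseline_reg
                res = _run_cell(case, ci, v, kwargs)
                if res is not None and baseline_reg is None:
                    baseline_reg = res.registration
                pairs.append((v, res))
        else:
            pairs = (
                (v, _run_cell(case, ci, v, {**base, spec.parameter: _scalar(v)}))
                for v in spec.values
            )
        for v, res in pairs:
            rows.append(_row(ci, v, res))
    return SweepResult(spec, pd.DataFrame(rows))


def _run_cell(case, case_id, value, kwargs):
    """One (case, value) pipeline run; stage failures (e.g. an empty mask
    at an extreme threshold) flag the cell as excluded instead of aborting
    the sweep."""
    import warnings

    try:
        return run_phantom_case(case, **kwargs)
    except ValueError as exc:
        warnings.warn(
            f"sweep cell (case {case_id}, value {value}) failed and is "
            f"excluded: {exc}",
            stacklevel=2,
        )
        return None


def _row(case_id: int, value, res: CaseResult | None) -> dict:
    if res is None:
        return {
            "case_id": case_id,
            "value": _scalar(value),
            "r_s_jac": float("nan"),
            "r_s_hu": float("nan"),
            "self_corr": float("nan"),
            "pct_neg_jac": float("nan"),
            "mse_after": float("nan"),
            "mse_before": float("nan"),
            "excluded": True,
        }
    return {
        "case_id": case_id,
        "value": _scalar(value),
        "r_s_jac": res.r_s_jac.r,
        "r_s_hu": res.r_s_hu.r,
        "self_corr": res.self_corr.r,
        "pct_neg_jac": res.pct_neg_jac,
        "mse_after": res.registration.mse_after,
        "mse_before": res.registration.mse_before,
        "excluded": res.excluded,
    }


def robust_range(
    result: SweepResult, method: str = "r_s_jac", tolerance: float = 0.10
) -> RobustRange:
    """Find the robust parameter range for one method.

    A value qualifies when its cohort mean r_S is within ``tolerance``
    (relative) of the highest observed qualifying mean and no case shows
    negative Jacobian values at that value.  The range returned is the
    maximal contiguous run (in sweep order) containing the argmax.
    """
    means = result.means()
    r = means[method].to_numpy(dtype=float)
    neg = means["any_neg_jac"].to_numpy(dtype=bool)
    ok = ~neg & np.isfinite(r)
    param = result.spec.parameter
    if not ok.any():
        return RobustRange(param, method, None, None, float("nan"), tolerance, empty=True)
    best = float(np.nanmax(r[ok]))
    qualifies = ok & (r >= (1.0 - tolerance) * best)
    argmax = int(np.flatnonzero(ok & (r == best))[0])
    lo_i = argmax
    while lo_i > 0 and qualifies[lo_i - 1]:
        lo_i -= 1
    hi_i = argmax
    while hi_i < len(r) - 1 and qualifies[hi_i + 1]:
        hi_i += 1
    values = [_scalar(v) for v in result.spec.values]
    return RobustRange(param, method, values[lo_i], values[hi_i], best, tolerance)


def optimize_lambda_by_self_correlation(result: SweepResult) -> float:
    """lambda* = argmax of the cohort-mean self-correlation (ties -> smaller)."""
    if result.spec.parameter != "dir_lambda":
        raise ValueError("requires a lambda sweep")
    means = result.means()
    s = means["self_corr"].to_numpy(dtype=float)
    if not np.isfinite(s).any():
        raise ValueError("self-correlation is empty for every lambda")
    best = np.nanmax(s)
    idx = int(np.flatnonzero(s == best)[0])  # sweep order is ascending lambda
    return float(means.index[idx])
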