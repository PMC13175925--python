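"""Per-case lung volume/density indices and their association with accuracy.

Factors mirror standard expiratory-CT physiology: whole-lung volumes in
both phases, absolute and percentage volume change on inspiration, mean
lung HU, percentage of air trapping (exhale-lung voxels below -850 HU,
an emphysema / small-airway marker), and the coefficient of variation of
lung density (heterogeneity).  Density-derived factors are computed on
the exhale phase; the CoV is taken on density (HU + 1000) to avoid the
sign change of raw HU around zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .validation_stats import CorrelationReport, pearson_ci
from .volumes_io import BinaryMask, ScalarVolume

__all__ = ["PatientFactors", "compute_factors", "factor_accuracy_table", "factors_frame"]

AIR_TRAPPING_HU = -850.0


@dataclass(frozen=True)
class PatientFactors:
    volume_inhale_l: float
    volume_exhale_l: float
    delta_volume_l: float
    delta_volume_pct: float
    mean_hu: float
    air_trapping_pct: float
    cov: float


def compute_factors(
    inhale_ct: ScalarVolume,
    exhale_ct: ScalarVolume,
    inhale_mask: BinaryMask,
    exhale_mask: BinaryMask,
) -> PatientFactors:
    """Lung volume and density indices for one case."""
    if inhale_mask.n_true == 0 or exhale_mask.n_true == 0:
        raise ValueError("lung masks must be nonempty")
    v_in = inhale_mask.volume_liters()
    v_ex = exhale_mask.volume_liters()
    hu_ex = np.asarray(exhale_ct.values, dtype=float)[exhale_mask.values]
    dens = np.maximum(hu_ex + 1000.0, 0.0)
    mean_dens = float(dens.mean())
    return PatientFactors(
        volume_inhale_l=v_in,
        volume_exhale_l=v_ex,
        delta_volume_l=v_in - v_ex,
        delta_volume_pct=100.0 * (v_in - v_ex) / v_ex,
        mean_hu=float(hu_ex.mean()),
        air_trapping_pct=100.0 * float((hu_ex < AIR_TRAPPING_HU).mean()),
        cov=float(dens.std(ddof=0) / mean_dens) if mean_dens > 0 else float("nan"),
    )


def factors_frame(factors: Sequence[PatientFactors], case_ids: Sequence | None = None) -> pd.DataFrame:
    """One row per case, columns: case_id, vol_in_L, vol_ex_L, dvol_L,
    dvol_pct, mean_hu, air_trap_pct, cov."""
    ids = list(case_ids) if case_ids is not None else list(range(len(factors)))
    rows = []
    for cid, f in zip(ids, factors):
        rows.append(
            {
                "case_id": cid,
                "vol_in_L": f.volume_inhale_l,
                "vol_ex_L": f.volume_exhale_l,
                "dvol_L": f.delta_volume_l,
                "dvol_pct": f.delta_volume_pct,
                "mean_hu": f.mean_hu,
                "air_trap_pct": f.air_trapping_pct,
                "cov": f.cov,
            }
        )
    return pd.DataFrame(rows)


_FACTOR_LABELS = {
    "dvol_pct": "Percentage change in lung volume",
    "vol_ex_L": "Lung volume at peak exhale",
    "dvol_L": "Absolute change in lung volume",
    "air_trap_pct": "Percentage of air trapping (< -850 HU)",
    "mean_hu": "Mean HU",
    "cov": "Coefficient of variation",
    "vol_in_L": "Lung volume at peak inhale",
}


def factor_accuracy_table(
    factors: Sequence[PatientFactors],
    accuracy: dict[str, Sequence[float]],
) -> pd.DataFrame:
    """Pearson correlation of each factor with per-case accuracy, per method.

    ``accuracy`` maps a method name (e.g. "Jac", "HU") to one r_S value per
    case.  Returns columns (factor, method, r, ci_lo, ci_hi, p, n).
    """
    frame = factors_frame(factors)
    rows = []
    for key, label in _FACTOR_LABELS.items():
        x = frame[key].to_numpy()
        for method, acc in accuracy.items():
            acc = np.asarray(acc, dtype=float)
            if acc.size != len(factors):
                raise ValueError("accuracy length must match the factor list")
            rep: CorrelationReport = pearson_ci(x, acc)
            rows.append(
                {
                    "factor": label,
                    "method": method,
                    "r": rep.r,
                    "ci_lo": rep.ci95[0] if rep.ci95 else float("nan"),
                    "ci_hi": rep.ci95[1] if rep.ci95 else float("nan"),
                    "p": rep.p,
                    "n": rep.n,
                }
            )
    return pd.DataFrame(rows)
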