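"""Accuracy statistics: masked Spearman validation, self-correlation,
Pearson correlations with Fisher-z intervals, and paired t-tests.

The accuracy metric throughout is the voxel-wise Spearman rank correlation
r_S between a ventilation image (resampled to the reference grid) and the
reference ventilation, computed over lung voxels.  Rank correlation is the
natural choice when two modalities are interpreted in terms of relative
(high/medium/low) rather than quantitative ventilation.

The self-correlation quality metric is the Spearman correlation between a
paired Jacobian-based and HU-based ventilation image: it needs no ground
truth, and tracks accuracy because both metrics degrade together when the
registration degrades.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .volumes_io import BinaryMask, GeometryError, ScalarVolume

__all__ = [
    "CorrelationReport",
    "spearman_masked",
    "self_correlation",
    "pearson_ci",
    "paired_ttest",
]


@dataclass(frozen=True)
class CorrelationReport:
    """A correlation coefficient with CI, p-value, and sample size.

    ``defined`` is False for degenerate inputs (zero variance); the numeric
    fields are then NaN.
    """

    kind: Literal["spearman", "pearson"]
    r: float
    p: float
    n: int
    ci95: tuple[float, float] | None = None
    defined: bool = True

    @staticmethod
    def undefined(kind: str, n: int) -> "CorrelationReport":
        return CorrelationReport(kind, float("nan"), float("nan"), n, None, defined=False)


def _masked_pairs(a: ScalarVolume, b: ScalarVolume, mask: BinaryMask):
    if a.grid != b.grid or a.grid != mask.grid:
        raise GeometryError("volumes and mask must share one grid")
    m = mask.values & a.valid_mask() & b.valid_mask()
    x = np.asarray(a.values, dtype=float)[m]
    y = np.asarray(b.values, dtype=float)[m]
    finite = np.isfinite(x) & np.isfinite(y)
    return x[finite], y[finite]


def spearman_masked(a: ScalarVolume, b: ScalarVolume, mask: BinaryMask) -> CorrelationReport:
    """Voxel-wise Spearman correlation over valid mask voxels.

    Ranks use average-rank tie handling; r is the Pearson correlation of
    the ranks.  Requires at least 3 valid voxels; constant input yields an
    undefined-flagged report.
    """
    x, y = _masked_pairs(a, b, mask)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 valid mask voxels, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport.undefined("spearman", n)
    r, p = stats.spearmanr(x, y)
    return CorrelationReport("spearman", float(r), float(p), int(n))


def self_correlation(vj, vh, mask: BinaryMask) -> CorrelationReport:
    """Spearman correlation between paired Jacobian- and HU-based images.

    A ground-truth-free quality surrogate; accepts the two
    :class:`~ctvi_lab.ventilation.VentilationImage` halves of one case.
    """
    return spearman_masked(vj.volume, vh.volume, mask)


def pearson_ci(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Pearson r with Fisher-z 95% CI and two-sided t-test p-value.

    CI: tanh(atanh(r) +/- 1.96 / sqrt(n - 3)); p from
    t = r sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport.undefined("pearson", n)
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        p = 0.0
        ci = (r, r) if n <= 3 else tuple(
            float(np.tanh(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)) + s * 1.96 / np.sqrt(n - 3)))
            for s in (-1, 1)
        )
        return CorrelationReport("pearson", r, p, n, ci)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationReport("pearson", r, p, n, ci)


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired t-test p-value; NaN when differences are constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError(f"need n >= 2, got {x.size}")
    d = x - y
    if np.ptp(d) == 0:
        if np.allclose(d, 0):
            return 1.0
        return float("nan")
    res = stats.ttest_rel(x, y)
    return float(res.pvalue)
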