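"""Sweep orchestration, robust-range criterion, and lambda optimization."""

import numpy as np
import pandas as pd
import pytest

from ctvi_lab import (
    RegistrationStage,
    default_sweeps,
    generate_phantom,
    optimize_lambda_by_self_correlation,
    robust_range,
    run_sweep,
)
from ctvi_lab.pipeline import run_phantom_case
from ctvi_lab.sensitivity import BASELINE, SweepResult, SweepSpec
from conftest import small_spec

FAST_STAGES = (
    RegistrationStage(32.0, image_downsample=2, max_iterations=60),
    RegistrationStage(16.0, image_downsample=1, max_iterations=60),
)


def _fabricated(values, means, neg_pcts, parameter="dir_lambda", self_corr=None):
    rows = []
    for v, m, neg in zip(values, means, neg_pcts):
        rows.append(
            {
                "case_id": 0,
                "value": v,
                "r_s_jac": m,
                "r_s_hu": m,
                "self_corr": m if self_corr is None else self_corr[values.index(v)],
                "pct_neg_jac": neg,
                "mse_after": 1.0,
                "mse_before": 2.0,
                "excluded": neg > 0,
            }
        )
    return SweepResult(SweepSpec(parameter, tuple(values)), pd.DataFrame(rows))


class TestDefaultSweeps:
    def test_threshold_grid(self):
        spec = next(s for s in default_sweeps() if s.parameter == "lung_threshold_hu")
        assert len(spec.values) == 10
        assert spec.values[0] == -600.0 and spec.values[-1] == -150.0
        assert np.allclose(np.diff(spec.values), 50.0)

    def test_lambda_grid(self):
        spec = next(s for s in default_sweeps() if s.parameter == "dir_lambda")
        assert len(spec.values) == 18
        assert spec.values[0] == pytest.approx(0.05)
        assert spec.values[-1] == pytest.approx(100.0)
        ratios = np.diff(np.log(spec.values))
        assert np.allclose(ratios, ratios[0])  # geometric spacing

    def test_diameter_grid(self):
        spec = next(s for s in default_sweeps() if s.parameter == "filter_diameter_vox")
        assert tuple(spec.values) == (0, 3, 5, 7, 9)

    def test_baseline_values(self):
        assert BASELINE == {"lung_threshold_hu": -250.0, "dir_lambda": 1.0, "filter_diameter_vox": 3}


class TestRobustRange:
    def test_hand_enumerated_example(self):
        res = _fabricated([1.0, 2.0, 3.0, 4.0, 5.0], [0.40, 0.55, 0.60, 0.58, 0.30], [5.0, 0, 0, 0, 0])
        rr = robust_range(res, "r_s_jac")
        assert (rr.lo, rr.hi) == (2.0, 4.0)
        assert rr.max_mean_r == pytest.approx(0.60)

    def test_single_qualifying_value(self):
        res = _fabricated([1.0], [0.5], [0.0])
        rr = robust_range(res)
        assert (rr.lo, rr.hi) == (1.0, 1.0) and not rr.empty

    def test_all_folding_is_empty_flagged(self):
        res = _fabricated([1.0, 2.0], [0.5, 0.6], [1.0, 2.0])
        assert robust_range(res).empty

    def test_matches_bruteforce_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(1, 21))
            means = rng.uniform(0, 1, n).round(3)
            neg = (rng.random(n) < 0.25) * rng.uniform(0.1, 3.0, n)
            values = [float(v) for v in np.arange(1, n + 1)]
            res = _fabricated(values, list(means), list(neg))
            rr = robust_range(res, "r_s_jac")
            ok = neg == 0
            if not ok.any():
                assert rr.empty
                continue
            best = means[ok].max()
            argmax = int(np.flatnonzero(ok & (means == best))[0])
            qual = ok & (means >= 0.9 * best)
            # longest contiguous interval containing the argmax, all qualifying
            best_interval = None
            for i in range(n):
                for j in range(i, n):
                    if i <= argmax <= j and qual[i : j + 1].all():
                        if best_interval is None or (j - i) > (best_interval[1] - best_interval[0]):
                            best_interval = (i, j)
            assert best_interval is not None
            assert (rr.lo, rr.hi) == (values[best_interval[0]], values[best_interval[1]])


class TestOptimizeLambda:
    def test_argmax(self):
        res = _fabricated([0.5, 1.0, 2.0], [0, 0, 0], [0, 0, 0], self_corr=[0.2, 0.8, 0.5])
        assert optimize_lambda_by_self_correlation(res) == 1.0

    def test_tie_prefers_smaller_lambda(self):
        res = _fabricated([1.0, 2.0], [0, 0], [0, 0], self_corr=[0.8, 0.8])
        assert optimize_lambda_by_self_correlation(res) == 1.0

    def test_requires_lambda_sweep(self):
        res = _fabricated([0, 3], [0.5, 0.6], [0, 0], parameter="filter_diameter_vox")
        with pytest.raises(ValueError):
            optimize_lambda_by_self_correlation(res)


class TestRunSweep:
    @pytest.fixture(scope="class")
    def case(self):
        return generate_phantom(small_spec(seed=21))

    def test_single_cell_matches_manual_pipeline(self, case):
        spec = SweepSpec("lung_threshold_hu", (-250.0,))
        result = run_sweep([case], spec, stages=FAST_STAGES)
        manual = run_phantom_case(case, stages=FAST_STAGES)
        row = result.table.iloc[0]
        assert row.r_s_jac == pytest.approx(manual.r_s_jac.r)
        assert row.r_s_hu == pytest.approx(manual.r_s_hu.r)
        assert row.mse_after == pytest.approx(manual.registration.mse_after)

    def test_filter_sweep_zero_diameter_equals_unsmoothed_baseline(self, case):
        spec = SweepSpec("filter_diameter_vox", (0,))
        result = run_sweep([case], spec, stages=FAST_STAGES)
        manual = run_phantom_case(case, filter_diameter_vox=0, stages=FAST_STAGES)
        assert result.table.iloc[0].r_s_jac == pytest.approx(manual.r_s_jac.r)

    def test_exclusion_rule_removes_folding_cells_from_means(self):
        table = pd.DataFrame(
            [
                {"case_id": 0, "value": 1.0, "r_s_jac": 0.9, "r_s_hu": 0.9, "self_corr": 0.9,
                 "pct_neg_jac": 0.0, "mse_after": 1.0, "mse_before": 2.0, "excluded": False},
                {"case_id": 1, "value": 1.0, "r_s_jac": 0.1, "r_s_hu": 0.1, "self_corr": 0.1,
                 "pct_neg_jac": 2.0, "mse_after": 1.0, "mse_before": 2.0, "excluded": True},
            ]
        )
        res = SweepResult(SweepSpec("dir_lambda", (1.0,)), table)
        means = res.means()
        assert means.loc[1.0, "r_s_jac"] == pytest.approx(0.9)
        assert bool(means.loc[1.0, "any_neg_jac"])

    def test_empty_case_list_rejected(self):
        with pytest.raises(ValueError):
            run_sweep([], SweepSpec("dir_lambda", (1.0,)))
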