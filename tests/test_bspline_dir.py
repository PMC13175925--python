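"""Registration operators: warping, Jacobian, QA metrics, and recovery."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from ctvi_lab import (
    BinaryMask,
    DisplacementField,
    RegistrationConfig,
    RegistrationStage,
    ScalarVolume,
    VolumeGrid,
    compute_jacobian_map,
    generate_phantom,
    masked_mse,
    percent_mse_decrease,
    percent_negative_jacobian,
    register,
    union_mask,
    warp,
)
from ctvi_lab.bspline_dir import _basis_matrix, _n_ctrl, _tensor_apply
from conftest import small_spec

FAST_STAGES = (
    RegistrationStage(32.0, image_downsample=2, max_iterations=100),
    RegistrationStage(16.0, image_downsample=1, max_iterations=100),
)


class TestWarp:
    def test_zero_field_is_identity(self, rng):
        grid = VolumeGrid((8, 8, 8), (1, 1, 1))
        img = ScalarVolume(grid, rng.normal(size=grid.dims))
        out = warp(img, DisplacementField(grid, np.zeros(grid.dims + (3,))))
        np.testing.assert_allclose(out.values, img.values)

    def test_constant_field_exact_voxel_shift(self, rng):
        grid = VolumeGrid((10, 6, 6), (0.96, 1.0, 1.0))
        img = ScalarVolume(grid, rng.normal(size=grid.dims))
        u = np.zeros(grid.dims + (3,))
        u[..., 0] = 1.92  # exactly two voxels along x
        out = warp(img, DisplacementField(grid, u))
        np.testing.assert_allclose(out.values[:-2], img.values[2:], atol=1e-12)

    def test_ramp_image_warped_exactly(self, rng):
        grid = VolumeGrid((10, 10, 10), (1.0, 1.5, 2.0))
        cx, cy, cz = grid.coordinate_arrays()
        ramp = np.broadcast_to(2 * cx + 3 * cy - cz, grid.dims).copy()
        img = ScalarVolume(grid, ramp)
        u = rng.uniform(-1.5, 1.5, grid.dims + (3,))
        out = warp(img, DisplacementField(grid, u))
        expect = 2 * (cx + u[..., 0]) + 3 * (cy + u[..., 1]) - (cz + u[..., 2])
        inside = out.valid_mask()
        np.testing.assert_allclose(out.values[inside], expect[inside], atol=1e-6)


class TestJacobian:
    def test_zero_field(self):
        grid = VolumeGrid((6, 6, 6), (1, 1, 1))
        jac = compute_jacobian_map(DisplacementField(grid, np.zeros(grid.dims + (3,))))
        np.testing.assert_allclose(jac.values, 1.0)

    def test_linear_field_closed_form(self):
        grid = VolumeGrid((8, 8, 8), (1.0, 1.0, 2.0))
        cx, cy, _ = grid.coordinate_arrays()
        u = np.zeros(grid.dims + (3,))
        u[..., 0] = np.broadcast_to(0.05 * cx, grid.dims)
        u[..., 1] = np.broadcast_to(0.02 * cy, grid.dims)
        jac = compute_jacobian_map(DisplacementField(grid, u))
        np.testing.assert_allclose(jac.values[1:-1, 1:-1, 1:-1], 1.05 * 1.02, rtol=1e-12)

    def test_random_spline_field_vs_refined_differences(self, rng):
        """Central differences at grid resolution vs 10x finer differences
        of the same analytic spline."""
        grid = VolumeGrid((32, 32, 28), (1.0, 1.0, 1.25))
        spacing_ctrl = 16.0
        lo_hi = grid.extent()
        n_ctrl = tuple(_n_ctrl(lo, hi, spacing_ctrl) for lo, hi in lo_hi)
        coeff = rng.normal(0, 0.7, n_ctrl + (3,))

        def field_at(axes_coords):
            mats = [
                _basis_matrix(axes_coords[a], lo_hi[a][0], spacing_ctrl, n_ctrl[a])
                for a in range(3)
            ]
            return np.stack([_tensor_apply(mats, coeff[..., a]) for a in range(3)], -1)

        u = field_at([grid.axis_coords(a) for a in range(3)])
        jac = compute_jacobian_map(DisplacementField(grid, u))

        h = [s / 10.0 for s in grid.spacing]
        grads = {}
        for b in range(3):  # derivative axis
            axes_p = [grid.axis_coords(a) + (h[b] if a == b else 0.0) for a in range(3)]
            axes_m = [grid.axis_coords(a) - (h[b] if a == b else 0.0) for a in range(3)]
            grads[b] = (field_at(axes_p) - field_at(axes_m)) / (2 * h[b])
        det = np.zeros(grid.dims)
        g = np.zeros(grid.dims + (3, 3))
        for a in range(3):
            for b in range(3):
                g[..., a, b] = grads[b][..., a]
            g[..., a, a] += 1.0
        det = np.linalg.det(g)
        interior = (slice(2, -2),) * 3
        rel = np.abs(jac.values[interior] - det[interior]) / np.abs(det[interior])
        assert rel.max() < 1e-3


class TestQAMetrics:
    def _mask(self, grid, frac=1.0):
        m = np.ones(grid.dims, bool)
        return BinaryMask(grid, m)

    def test_identity_has_no_folding(self):
        grid = VolumeGrid((6, 6, 6), (1, 1, 1))
        jac = compute_jacobian_map(DisplacementField(grid, np.zeros(grid.dims + (3,))))
        assert percent_negative_jacobian(jac, self._mask(grid)) == 0.0

    def test_analytic_fold_is_fully_negative(self):
        grid = VolumeGrid((8, 8, 8), (1, 1, 1))
        cx, _, _ = grid.coordinate_arrays()
        u = np.zeros(grid.dims + (3,))
        u[..., 0] = np.broadcast_to(-2.0 * cx, grid.dims)  # det = -1 everywhere
        jac = compute_jacobian_map(DisplacementField(grid, u))
        assert percent_negative_jacobian(jac, self._mask(grid)) == 100.0

    def test_crafted_fraction(self):
        grid = VolumeGrid((10, 10, 10), (1, 1, 1))
        vals = np.ones(grid.dims)
        vals.ravel()[:3] = -0.5
        mask = np.zeros(grid.dims, bool)
        mask.ravel()[:1000] = True
        pct = percent_negative_jacobian(ScalarVolume(grid, vals), BinaryMask(grid, mask))
        assert pct == pytest.approx(0.3)

    def test_masked_mse_and_decrease(self):
        grid = VolumeGrid((4, 4, 4), (1, 1, 1))
        a = ScalarVolume(grid, np.zeros(grid.dims))
        b = ScalarVolume(grid, np.full(grid.dims, 10.0))
        m = self._mask(grid)
        assert masked_mse(a, a, m) == 0.0
        assert masked_mse(a, b, m) == pytest.approx(100.0)
        assert percent_mse_decrease(400.0, 100.0) == pytest.approx(75.0)
        assert np.isnan(percent_mse_decrease(0.0, 0.0))


class TestRegister:
    def test_identical_images_stay_put(self, small_case):
        ex = small_case.exhale_ct
        mask = small_case.truth_mask
        res = register(ex, ex, mask, RegistrationConfig(stages=FAST_STAGES))
        assert res.mse_after <= max(res.mse_before, 1.0)
        assert np.abs(res.dvf.vectors).mean() < 0.3

    def test_translation_recovery_within_half_slice(self, small_case_clean):
        ex = small_case_clean.exhale_ct
        shift_mm = 3.0
        shift_vox = shift_mm / ex.grid.spacing[2]
        # moving(y) = fixed(y - 3mm z) so that moving(x + u) = fixed(x) at u = +3 mm
        moving = ScalarVolume(ex.grid, ndimage.shift(ex.values, (0, 0, shift_vox), order=1, mode="nearest"))
        mask = small_case_clean.truth_mask
        res = register(moving, ex, mask, RegistrationConfig(stages=FAST_STAGES))
        core = ndimage.binary_erosion(mask.values, iterations=3)
        uz = res.dvf.vectors[..., 2][core]
        assert np.abs(uz - shift_mm).mean() < 0.9

    def test_huge_lambda_freezes_field(self, small_case):
        res = register(
            small_case.inhale_ct,
            small_case.exhale_ct,
            small_case.truth_mask,
            RegistrationConfig(dir_lambda=1.0e6, stages=FAST_STAGES),
        )
        assert np.linalg.norm(res.dvf.vectors, axis=-1).mean() < 0.1

    def test_cost_trace_is_consistent_and_decreasing(self, small_case):
        res = register(
            small_case.inhale_ct,
            small_case.exhale_ct,
            union_mask(small_case.truth_mask, small_case.truth_mask_inhale),
            RegistrationConfig(stages=FAST_STAGES),
        )
        lam = res.config.dir_lambda
        by_stage = {}
        for rec in res.cost_trace:
            assert rec["C"] == pytest.approx(rec["C_sim"] + lam * rec["C_reg"], rel=1e-9)
            by_stage.setdefault(rec["stage"], []).append(rec["C"])
        for costs in by_stage.values():
            diffs = np.diff(costs)
            assert (diffs <= 1e-6 * np.abs(costs[0])).all()

    def test_empty_mask_rejected(self, small_case):
        empty = BinaryMask(small_case.exhale_ct.grid, np.zeros(small_case.exhale_ct.grid.dims, bool))
        with pytest.raises(ValueError):
            register(small_case.inhale_ct, small_case.exhale_ct, empty)
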