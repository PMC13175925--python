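"""Phantom generator: closed-form truth, mass conservation, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from ctvi_lab import DeformationSpec, PhantomSpec, generate_phantom, truth_displacement
from ctvi_lab.phantom import SpecError, cohort_specs, default_cohort, _axis_displacement
from conftest import small_spec


def _no_deformation():
    return DeformationSpec(
        expand=(0, 0, 0), bump=(0, 0, 0), gradient=(0, 0, 0), defect_depth=0.0
    )


class TestTruthDisplacement:
    def test_zero_deformation_gives_identity(self):
        spec = small_spec(deformation=_no_deformation())
        u, jac = truth_displacement(spec, (10.0, 20.0, 30.0))
        assert np.allclose(u, 0.0) and jac == pytest.approx(1.0)

    def test_uniform_expansion_jacobian_is_product(self):
        spec = small_spec(
            deformation=DeformationSpec(
                expand=(0.05, 0.02, 0.0), bump=(0, 0, 0), gradient=(0, 0, 0), defect_depth=0.0
            )
        )
        for point in [(5.0, 5.0, 5.0), (40.0, 60.0, 90.0)]:
            _, jac = truth_displacement(spec, point)
            assert jac == pytest.approx(1.05 * 1.02, rel=1e-12)

    def test_analytic_jacobian_matches_finite_differences(self):
        # central differences of the sampled displacement at 0.1 mm step
        rng = np.random.default_rng(3)
        h = 0.1
        for _ in range(10):
            effort = rng.uniform(0.4, 0.85)
            spec = small_spec(
                deformation=DeformationSpec(
                    expand=tuple(effort * e for e in (0.01, 0.01, 0.05)),
                    bump=tuple(effort * b for b in (0.015, 0.015, 0.26)),
                    bump_center_offset_mm=(0, 0, float(rng.uniform(-12, -6))),
                    defect_depth=float(rng.uniform(0, 0.9)),
                    defect_radius_mm=float(rng.uniform(8, 15)),
                )
            )
            pts = np.column_stack(
                [rng.uniform(lo + 1, hi - 1, 40) for lo, hi in spec.ct_grid.extent()]
            )
            _, jac = truth_displacement(spec, (pts[:, 0], pts[:, 1], pts[:, 2]))
            fd = np.ones(len(pts))
            for a in range(3):
                up, _ = _axis_displacement(spec, a, pts[:, a] + h)
                um, _ = _axis_displacement(spec, a, pts[:, a] - h)
                fd *= 1.0 + (up - um) / (2 * h)
            assert np.max(np.abs(fd - jac) / jac) < 1e-4

    def test_diffeomorphism_for_valid_specs(self):
        for seed, spec in enumerate(cohort_specs(10, base_seed=5)):
            cx, cy, cz = spec.ct_grid.coordinate_arrays()
            _, jac = truth_displacement(spec, (cx, cy, cz))
            assert jac.min() > 0, f"case {seed} folds"

    def test_non_diffeomorphic_spec_rejected(self):
        spec = small_spec(
            deformation=DeformationSpec(expand=(0.0, 0.0, -1.05), bump=(0, 0, 0))
        )
        with pytest.raises(SpecError):
            spec.validate()


class TestGeneratePhantom:
    def test_zero_deformation_makes_identical_phases(self):
        spec = small_spec(
            deformation=_no_deformation(), ct_noise_sd=0.0, ref_noise_sd=0.0, blood_shift=0.0
        )
        case = generate_phantom(spec)
        np.testing.assert_allclose(case.inhale_ct.values, case.exhale_ct.values, atol=1e-9)

    def test_uniform_expansion_reference_before_blur(self):
        # J = 1.1**2 * 1.0 uniformly; unblurred reference equals J - 1 in-mask
        spec = small_spec(
            deformation=DeformationSpec(
                expand=(0.1, 0.1, 0.0), bump=(0, 0, 0), gradient=(0, 0, 0), defect_depth=0.0
            ),
            ct_noise_sd=0.0,
            ref_noise_sd=0.0,
            ref_blur_fwhm_mm=0.0,
        )
        case = generate_phantom(spec)
        ref = case.reference_ventilation
        # sample reference voxels deep inside the lung
        from ctvi_lab import resample_nearest, ScalarVolume

        mask_on_ref = resample_nearest(
            ScalarVolume(spec.ct_grid, case.truth_mask.values.astype(float)), ref.grid
        )
        inside = mask_on_ref.values > 0.5
        vals = ref.values[inside]
        assert np.median(np.abs(vals - (1.1**2 - 1.0))) < 1e-3

    def test_mass_conservation_between_phases(self):
        # full-resolution grid: the 1% tolerance reflects discretization of
        # the displaced lung boundary, which the coarse test grid exceeds
        spec = PhantomSpec(seed=3, ct_noise_sd=0.0, ref_noise_sd=0.0, blood_shift=0.0)
        case = generate_phantom(spec)
        m_ex = (case.exhale_ct.values[case.truth_mask.values] + 1000.0).sum()
        m_in = (case.inhale_ct.values[case.truth_mask_inhale.values] + 1000.0).sum()
        assert abs(m_in - m_ex) / m_ex < 0.01

    def test_truth_jacobian_matches_closed_form_on_grid(self):
        spec = small_spec()
        case = generate_phantom(spec)
        cx, cy, cz = spec.ct_grid.coordinate_arrays()
        _, jac = truth_displacement(spec, (cx, cy, cz))
        np.testing.assert_allclose(case.truth_jacobian.values, np.broadcast_to(jac, spec.ct_grid.dims), rtol=1e-12)

    def test_determinism_identical_seed(self):
        a = generate_phantom(small_spec(seed=11))
        b = generate_phantom(small_spec(seed=11))
        np.testing.assert_array_equal(a.exhale_ct.values, b.exhale_ct.values)
        np.testing.assert_array_equal(a.inhale_ct.values, b.inhale_ct.values)
        np.testing.assert_array_equal(
            a.reference_ventilation.values, b.reference_ventilation.values
        )

    def test_reference_ceiling_brackets_accuracy(self):
        """The blurred/noisy reference sets a rank-correlation ceiling for
        the exact truth Jacobian: high but below 1 (blur + resampling),
        lower with reference noise."""
        from ctvi_lab import PhantomSpec, ctvi_jacobian
        from ctvi_lab.pipeline import validate_against_reference

        clean = generate_phantom(PhantomSpec(seed=4, ct_noise_sd=0.0, ref_noise_sd=0.0))
        noisy = generate_phantom(PhantomSpec(seed=4))
        r_clean = validate_against_reference(
            ctvi_jacobian(clean.truth_jacobian), clean.reference_ventilation, clean.truth_mask
        ).r
        r_noisy = validate_against_reference(
            ctvi_jacobian(noisy.truth_jacobian), noisy.reference_ventilation, noisy.truth_mask
        ).r
        assert 0.93 <= r_clean < 1.0
        assert 0.80 <= r_noisy < r_clean

    def test_reference_grid_spacing(self):
        case = generate_phantom(small_spec())
        assert case.reference_ventilation.grid.spacing == pytest.approx((2.04, 2.04, 2.2))


class TestCohort:
    def test_cohort_deterministic(self):
        a = default_cohort(2, base_seed=1)
        b = default_cohort(2, base_seed=1)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.exhale_ct.values, cb.exhale_ct.values)

    def test_volume_change_spans_twofold_range(self):
        # percentage volume change computed analytically from each spec
        spans = []
        for spec in cohort_specs(14, base_seed=0):
            cx, cy, cz = spec.ct_grid.coordinate_arrays()
            _, jac = truth_displacement(spec, (cx, cy, cz))
            jac = np.broadcast_to(jac, spec.ct_grid.dims)
            # lung membership from the ellipsoid geometry
            pts = np.stack(np.meshgrid(*(spec.ct_grid.axis_coords(a) for a in range(3)), indexing="ij"), -1)
            inside = np.zeros(spec.ct_grid.dims, bool)
            for lc in spec.lung_centers_mm():
                inside |= (((pts - np.asarray(lc)) / np.asarray(spec.lung_semiaxes_mm)) ** 2).sum(-1) < 1
            spans.append(100.0 * (jac[inside].mean() - 1.0))
        assert max(spans) / min(spans) >= 2.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            default_cohort(0)
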