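"""Synthetic inhale/exhale lung-phantom generator with exact ground truth.

A phantom "patient" is a continuous material model — a soft-tissue body
ellipsoid containing two lung ellipsoids of noisy low-density parenchyma
threaded by bright vessels — deformed by a separable, analytically
invertible expansion field.  Because the displacement is separable
(u_x = f(x), u_y = g(y), u_z = h(z) with monotone per-axis profiles),
the Jacobian determinant has the closed form (1+f')(1+g')(1+h') and the
map is inverted exactly by three 1-D monotone root-finds.

The inhale CT is rendered analytically from the material model at the
inverse-mapped coordinates with tissue-mass-conserving intensities,

    density_in(X) = density_ex(x) / J(x) * (1 + beta),   X = x + u(x),

i.e. HU_in = -1000 + (HU_ex + 1000) (1 + beta) / J, where ``beta`` is an
optional global "blood shift" mass change emulating blood redistribution
during inspiration.  Rendering from the continuous model (rather than
warping the discrete exhale image) keeps phantom truth free of
interpolation error.

The PET-like reference ventilation is rank-faithful to local volume
change: (J - 1) inside the lungs, Gaussian-blurred, resampled to a
coarser grid, plus additive noise.  Spearman validation is invariant to
any further monotone distortion, so blur + noise alone set the accuracy
ceiling of a phantom case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .volumes_io import BinaryMask, DisplacementField, ScalarVolume, VolumeGrid
from . import volumes_io

__all__ = [
    "DeformationSpec",
    "PhantomSpec",
    "PhantomCase",
    "SpecError",
    "truth_displacement",
    "generate_phantom",
    "default_cohort",
]

SQRT_HALF_PI = float(np.sqrt(np.pi / 2.0))


class SpecError(ValueError):
    """Phantom specification violates an invariant (e.g. non-diffeomorphic)."""


@dataclass(frozen=True)
class DeformationSpec:
    """Separable exhale-to-inhale expansion field.

    Per axis a with coordinate t over the grid extent [lo, hi], L = hi - lo
    and body center c0, the displacement derivative is

        u_a'(t) = expand_a
                + bump_a * exp(-(t - cb_a)^2 / (2 w_a^2))
                + gradient_a * cos(pi (t - lo) / L)
                - depth * A_a * exp(-(t - c_a)^2 / (2 r^2))

    integrated analytically with u_a(c0) = 0 (anchored at the body center
    c0; cb_a = c0_a + bump_center_offset_mm_a).  ``expand`` is a small
    uniform expansion fraction; ``bump`` concentrates most of the volume
    change over width ``bump_width_mm`` around cb, so the Jacobian is
    strongly heterogeneous while displacement stays bounded (the chest
    wall barely moves, like real breath-hold pairs).  Offsetting the z
    bump center inferiorly produces a diaphragm-driven sup-inf
    ventilation gradient.  The Gaussian dip carves a focal ventilation
    defect of radius ``defect_radius_mm`` at ``defect_center_mm`` with
    fractional ``defect_depth`` in [0, 1] (A_a is the local expansion
    rate at the defect center, so depth 1 flattens ventilation there).
    """

    expand: tuple[float, float, float] = (0.01, 0.01, 0.05)
    bump: tuple[float, float, float] = (0.015, 0.015, 0.26)
    bump_width_mm: tuple[float, float, float] = (26.0, 26.0, 20.0)
    bump_center_offset_mm: tuple[float, float, float] = (0.0, 0.0, -12.0)
    gradient: tuple[float, float, float] = (0.0, 0.0, 0.0)
    defect_center_mm: tuple[float, float, float] = (28.6, 45.6, 60.7)  # left lung center
    defect_radius_mm: float = 14.0
    defect_depth: float = 0.6


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic inhale/exhale case."""

    ct_grid: VolumeGrid = VolumeGrid((96, 96, 64), (0.96, 0.96, 1.8))
    ref_spacing: tuple[float, float, float] = (2.04, 2.04, 2.2)
    body_semiaxes_mm: tuple[float, float, float] = (43.0, 43.0, 55.0)
    lung_semiaxes_mm: tuple[float, float, float] = (16.0, 23.0, 38.0)
    lung_offset_mm: float = 17.0  # left/right lung center offset from body center
    lung_sup_shift_mm: float = 4.0  # lungs sit superior of center: diaphragm room
    parenchyma_hu_mean: float = -850.0
    parenchyma_hu_sd: float = 40.0
    vessel_count: int = 40
    vessel_radius_mm: float = 1.1  # Gaussian profile sigma
    edge_softness_mm: float = 0.7  # pleural/skin interface blur scale (logistic)
    deformation: DeformationSpec = field(default_factory=DeformationSpec)
    blood_shift: float = 0.0  # beta: global fractional mass change
    ct_noise_sd: float = 20.0  # HU
    ref_blur_fwhm_mm: float = 6.0
    ref_noise_sd: float = 0.02  # ventilation units
    seed: int = 0

    def center_mm(self) -> tuple[float, float, float]:
        g = self.ct_grid
        return tuple(g.origin[a] + 0.5 * (g.dims[a] - 1) * g.spacing[a] for a in range(3))

    def lung_centers_mm(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        cx, cy, cz = self.center_mm()
        cz = cz + self.lung_sup_shift_mm
        return (cx - self.lung_offset_mm, cy, cz), (cx + self.lung_offset_mm, cy, cz)

    def validate(self) -> None:
        if any(s <= 0 for s in self.body_semiaxes_mm + self.lung_semiaxes_mm):
            raise SpecError("semi-axes must be positive")
        if not 0.0 <= self.deformation.defect_depth <= 1.0:
            raise SpecError("defect_depth must lie in [0, 1]")
        # lungs strictly inside the body ellipsoid: sample lung surface points
        body = np.asarray(self.body_semiaxes_mm)
        center = np.asarray(self.center_mm())
        theta = np.linspace(0, np.pi, 9)
        phi = np.linspace(0, 2 * np.pi, 17)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        unit = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
        )
        for lc in self.lung_centers_mm():
            pts = np.asarray(lc) + unit * np.asarray(self.lung_semiaxes_mm)
            metric = (((pts - center) / body) ** 2).sum(axis=-1)
            if metric.max() >= 1.0:
                raise SpecError("lung ellipsoids must lie strictly inside the body")
        # diffeomorphism: 1 + u' > 0 along every axis, checked densely
        for axis in range(3):
            lo, hi = self.ct_grid.extent()[axis]
            t = np.linspace(lo, hi, 2049)
            _, du = _axis_displacement(self, axis, t)
            if (1.0 + du).min() <= 1e-3:
                raise SpecError(
                    f"deformation is not diffeomorphic along axis {axis}: "
                    f"min(1 + u') = {(1.0 + du).min():.4g}"
                )
        # inhale containment: displaced lung surfaces stay inside the body
        for lc in self.lung_centers_mm():
            pts = np.asarray(lc) + unit * np.asarray(self.lung_semiaxes_mm)
            moved = np.empty_like(pts)
            for axis in range(3):
                u, _ = _axis_displacement(self, axis, pts[..., axis])
                moved[..., axis] = pts[..., axis] + u
            metric = (((moved - center) / body) ** 2).sum(axis=-1)
            # margin: the pleural/skin blend tails must not merge across the
            # chest wall at any segmentation threshold, so the displaced lung
            # needs a few mm of clearance, not merely containment
            if metric.max() >= 0.95:
                raise SpecError(
                    "deformed (inhale) lung surface too close to the body "
                    "surface; reduce expansion/bump amplitudes"
                )


@dataclass
class PhantomCase:
    """Paired synthetic CTs, exact truth, and PET-like reference ventilation."""

    spec: PhantomSpec
    exhale_ct: ScalarVolume
    inhale_ct: ScalarVolume
    truth_mask: BinaryMask  # lungs on the exhale grid
    truth_mask_inhale: BinaryMask  # lungs on the inhale grid
    truth_dvf: DisplacementField
    truth_jacobian: ScalarVolume
    reference_ventilation: ScalarVolume

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        volumes_io.write_volume(self.exhale_ct, out / "exhale.nii.gz")
        volumes_io.write_volume(self.inhale_ct, out / "inhale.nii.gz")
        volumes_io.write_mask(self.truth_mask, out / "mask.nii.gz")
        volumes_io.write_mask(self.truth_mask_inhale, out / "mask_inhale.nii.gz")
        volumes_io.write_displacement_field(self.truth_dvf, out / "truth_dvf.nii.gz")
        volumes_io.write_volume(self.truth_jacobian, out / "truth_jac.nii.gz")
        volumes_io.write_volume(self.reference_ventilation, out / "reference.nii.gz")


# ---------------------------------------------------------------------------
# Analytic displacement
# ---------------------------------------------------------------------------

def _axis_displacement(spec: PhantomSpec, axis: int, t: np.ndarray):
    """u_a(t) and u_a'(t) along one axis (closed form).

    Anchored at the body center (u = 0 there), so the lungs expand about
    the thorax center rather than drifting toward the chest wall.
    """
    d = spec.deformation
    lo, hi = spec.ct_grid.extent()[axis]
    L = hi - lo
    c0 = spec.center_mm()[axis]
    t = np.asarray(t, dtype=float)
    s = t - lo
    s0 = c0 - lo
    e = d.expand[axis]
    b = d.bump[axis]
    w = d.bump_width_mm[axis]
    cb = c0 + d.bump_center_offset_mm[axis]
    g = d.gradient[axis]
    u = e * (t - c0) + g * (L / np.pi) * (np.sin(np.pi * s / L) - np.sin(np.pi * s0 / L))
    du = e + g * np.cos(np.pi * s / L)
    if b != 0.0:
        u = u + b * w * SQRT_HALF_PI * (
            erf((t - cb) / (w * np.sqrt(2.0))) - erf((c0 - cb) / (w * np.sqrt(2.0)))
        )
        du = du + b * np.exp(-((t - cb) ** 2) / (2.0 * w * w))
    if d.defect_depth > 0.0:
        c = d.defect_center_mm[axis]
        r = d.defect_radius_mm
        # dip amplitude cancels the local expansion rate at the defect center
        amp = d.defect_depth * (e + b * np.exp(-((c - cb) ** 2) / (2.0 * w * w)))
        if amp != 0.0:
            u = u - amp * r * SQRT_HALF_PI * (
                erf((t - c) / (r * np.sqrt(2.0))) - erf((c0 - c) / (r * np.sqrt(2.0)))
            )
            du = du - amp * np.exp(-((t - c) ** 2) / (2.0 * r * r))
    return u, du


def truth_displacement(spec: PhantomSpec, point: Sequence[float]):
    """Exact displacement vector (mm) and Jacobian determinant at a point.

    ``point`` may also carry arrays per component (broadcasting applies);
    the Jacobian is the analytic product (1+f')(1+g')(1+h').
    """
    spec.validate()
    u = []
    jac = 1.0
    for axis in range(3):
        ua, dua = _axis_displacement(spec, axis, np.asarray(point[axis], dtype=float))
        u.append(ua)
        jac = jac * (1.0 + dua)
    return tuple(u), jac


def _invert_axis(spec: PhantomSpec, axis: int, targets: np.ndarray) -> np.ndarray:
    """Solve t + u_a(t) = target per axis (monotone; Newton to < 1e-6 mm)."""
    lo, hi = spec.ct_grid.extent()[axis]
    pad = 0.3 * (hi - lo) + 10.0
    t_dense = np.linspace(lo - pad, hi + pad, 4096)
    u_dense, _ = _axis_displacement(spec, axis, t_dense)
    fwd = t_dense + u_dense
    t = np.interp(targets, fwd, t_dense)
    for _ in range(4):
        u, du = _axis_displacement(spec, axis, t)
        t = t - (t + u - targets) / (1.0 + du)
    return t


# ---------------------------------------------------------------------------
# Continuous material model
# ---------------------------------------------------------------------------

class _MaterialModel:
    """Noise-free exhale-phase HU as a function of material coordinates."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self.center = np.asarray(spec.center_mm())
        self.body = np.asarray(spec.body_semiaxes_mm)
        self.lungs = [np.asarray(c) for c in spec.lung_centers_mm()]
        self.lung_ax = np.asarray(spec.lung_semiaxes_mm)
        # band-limited random parenchyma texture: a sum of random cosine
        # modes with wavelengths 10-40 mm, unit variance.  Smooth (C-inf)
        # like PSF-limited CT, so trilinear sampling of the rendered images
        # carries only small interpolation error; identical in both phases.
        k_modes = 64
        dirs = rng.standard_normal((k_modes, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        wavelengths = np.exp(rng.uniform(np.log(10.0), np.log(40.0), k_modes))
        self._tex_freq = dirs * (2.0 * np.pi / wavelengths)[:, None]
        self._tex_phase = rng.uniform(0.0, 2.0 * np.pi, k_modes)
        self._tex_amp = np.sqrt(2.0 / k_modes)
        # vessels: line segments with Gaussian radial profiles (soft,
        # PSF-like edges).  Endpoints keep a fixed physical clearance from
        # the pleural surface (direction-dependent metric cap) so the whole
        # tube stays enclosed by parenchyma: a vessel piercing the pleura
        # would open the lung component to the body at strict segmentation
        # thresholds and defeat hole-filling.
        clearance = 1.75 * spec.vessel_radius_mm + 2.0
        def _interior_point(lc):
            while True:
                v = rng.uniform(-1.0, 1.0, 3)
                n = np.linalg.norm(v)
                if 1e-6 < n <= 1.0:
                    break
            w_unit = v / n
            r_phys = float(np.linalg.norm(w_unit * self.lung_ax))
            m_cap = max(1.0 - clearance / r_phys, 0.0)
            return lc + (n * m_cap) * w_unit * self.lung_ax

        self.segments = []
        for lc in self.lungs:
            for _ in range(max(spec.vessel_count // 2, 0)):
                self.segments.append((_interior_point(lc), _interior_point(lc)))

    def _texture(self, pts: np.ndarray) -> np.ndarray:
        phase = pts @ self._tex_freq.T + self._tex_phase
        return self._tex_amp * np.cos(phase).sum(axis=-1)

    def lung_indicator(self, pts: np.ndarray) -> np.ndarray:
        inside = np.zeros(pts.shape[:-1], dtype=bool)
        for lc in self.lungs:
            inside |= (((pts - lc) / self.lung_ax) ** 2).sum(axis=-1) < 1.0
        return inside

    def lung_soft_weight(self, pts: np.ndarray) -> np.ndarray:
        """Smooth lung membership in [0, 1]; logistic in approximate signed
        distance from the ellipsoid surface (positive inside)."""
        from scipy.special import expit

        s = max(self.spec.edge_softness_mm, 1e-3)
        w = np.zeros(pts.shape[:-1])
        for lc in self.lungs:
            rel = pts - lc
            m = np.sqrt((((rel) / self.lung_ax) ** 2).sum(axis=-1))
            r = np.linalg.norm(rel, axis=-1)
            dist = (1.0 - m) * r / np.maximum(m, 1e-6)
            w = np.maximum(w, expit(dist / s))
        return w

    def _vessel_weight(self, pts: np.ndarray) -> np.ndarray:
        """Soft vessel indicator in [0, 1]: Gaussian radial profile."""
        w = np.zeros(pts.shape[:-1])
        sigma2 = self.spec.vessel_radius_mm ** 2
        for a, b in self.segments:
            ab = b - a
            denom = float(ab @ ab)
            if denom < 1e-12:
                continue
            tt = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            closest = a + tt[..., None] * ab
            d2 = ((pts - closest) ** 2).sum(axis=-1)
            w = np.maximum(w, np.exp(-0.5 * d2 / sigma2))
        return w

    def body_soft_weight(self, pts: np.ndarray) -> np.ndarray:
        """Smooth body membership (soft outer skin edge, PSF-like)."""
        from scipy.special import expit

        s = max(self.spec.edge_softness_mm, 1e-3)
        rel = pts - self.center
        m = np.sqrt(((rel / self.body) ** 2).sum(axis=-1))
        r = np.linalg.norm(rel, axis=-1)
        dist = (1.0 - m) * r / np.maximum(m, 1e-6)
        return expit(dist / s)

    def hu(self, pts: np.ndarray) -> np.ndarray:
        """Exhale-phase HU at arbitrary material points (..., 3)."""
        spec = self.spec
        flat = pts.reshape(-1, 3)
        wb = self.body_soft_weight(flat)
        tissue = np.zeros(flat.shape[0])  # body soft tissue at 0 HU
        wl = self.lung_soft_weight(flat)
        near = wl > 1e-4
        if near.any():
            lung_pts = flat[near]
            hu = spec.parenchyma_hu_mean + spec.parenchyma_hu_sd * self._texture(lung_pts)
            wv = self._vessel_weight(lung_pts)
            paren = (1.0 - wv) * hu + wv * 50.0
            tissue[near] = wl[near] * paren
        out = -1000.0 + wb * (tissue + 1000.0)
        return out.reshape(pts.shape[:-1])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _reference_grid(spec: PhantomSpec) -> VolumeGrid:
    ct = spec.ct_grid
    dims = tuple(
        max(int(np.floor((ct.dims[a] - 1) * ct.spacing[a] / spec.ref_spacing[a])) + 1, 1)
        for a in range(3)
    )
    return VolumeGrid(dims, spec.ref_spacing, ct.origin)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom case; fully deterministic under ``spec.seed``."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng_model, rng_ex, rng_in, rng_ref = [np.random.default_rng(s) for s in root.spawn(4)]

    grid = spec.ct_grid
    model = _MaterialModel(spec, rng_model)

    cx, cy, cz = np.meshgrid(*(grid.axis_coords(a) for a in range(3)), indexing="ij")
    pts_ex = np.stack([cx, cy, cz], axis=-1)

    # exhale phase: material model sampled on the grid
    hu_ex = model.hu(pts_ex)
    mask_ex = model.lung_indicator(pts_ex)

    # exact truth on the exhale grid (1-D profiles broadcast to 3-D)
    u_axes, du_axes = [], []
    for axis in range(3):
        u1, du1 = _axis_displacement(spec, axis, grid.axis_coords(axis))
        sh = [1, 1, 1]
        sh[axis] = grid.dims[axis]
        u_axes.append(u1.reshape(sh))
        du_axes.append(du1.reshape(sh))
    shape = grid.dims
    vectors = np.stack([np.broadcast_to(u_axes[a], shape) for a in range(3)], axis=-1)
    jac = (1.0 + du_axes[0]) * (1.0 + du_axes[1]) * (1.0 + du_axes[2])
    jac = np.ascontiguousarray(np.broadcast_to(jac, shape))

    # inhale phase: invert the separable map, conserve tissue mass
    inv = [_invert_axis(spec, a, grid.axis_coords(a)) for a in range(3)]
    ix, iy, iz = np.meshgrid(*inv, indexing="ij")
    pts_in = np.stack([ix, iy, iz], axis=-1)
    du_inv = [_axis_displacement(spec, a, inv[a])[1] for a in range(3)]
    jac_at_inv = 1.0
    for axis in range(3):
        sh = [1, 1, 1]
        sh[axis] = grid.dims[axis]
        jac_at_inv = jac_at_inv * (1.0 + du_inv[axis].reshape(sh))
    hu_material_in = model.hu(pts_in)
    density_in = (hu_material_in + 1000.0) * (1.0 + spec.blood_shift) / jac_at_inv
    hu_in = density_in - 1000.0
    mask_in = model.lung_indicator(pts_in)

    if spec.ct_noise_sd > 0:
        hu_ex = hu_ex + rng_ex.normal(0.0, spec.ct_noise_sd, shape)
        hu_in = hu_in + rng_in.normal(0.0, spec.ct_noise_sd, shape)

    # PET-like reference: (J - 1) inside lungs, blurred, coarse grid, noisy
    vent = np.where(mask_ex, jac - 1.0, 0.0)
    if spec.ref_blur_fwhm_mm > 0:
        # mask-normalized blur: averages within the lung without diluting
        # boundary voxels against the zero exterior
        sigma_vox = [spec.ref_blur_fwhm_mm / 2.3548 / s for s in grid.spacing]
        num = gaussian_filter(vent, sigma=sigma_vox)
        den = gaussian_filter(mask_ex.astype(float), sigma=sigma_vox)
        vent = np.where(mask_ex, num / np.maximum(den, 1e-6), 0.0)
    ref_grid = _reference_grid(spec)
    ref = volumes_io.resample_linear(ScalarVolume(grid, vent, "ventilation"), ref_grid)
    if spec.ref_noise_sd > 0:
        ref = ScalarVolume(
            ref_grid,
            ref.values + rng_ref.normal(0.0, spec.ref_noise_sd, ref_grid.dims),
            "ventilation",
            ref.valid,
        )

    return PhantomCase(
        spec=spec,
        exhale_ct=ScalarVolume(grid, hu_ex, "HU"),
        inhale_ct=ScalarVolume(grid, hu_in, "HU"),
        truth_mask=BinaryMask(grid, mask_ex),
        truth_mask_inhale=BinaryMask(grid, mask_in),
        truth_dvf=DisplacementField(grid, vectors),
        truth_jacobian=ScalarVolume(grid, jac, "dimensionless"),
        reference_ventilation=ref,
    )


def analytic_deformed_inhale(spec: PhantomSpec) -> ScalarVolume:
    """Exact deformed-inhale CT on the exhale grid, free of interpolation.

    The deformed inhale is inhale(x + u(x)); with the analytic material
    model this collapses to HU(x) = -1000 + (HU_ex(x) + 1000)(1 + beta)/J(x)
    evaluated in closed form (noise-free).  Useful as an exact oracle for
    the HU-based ventilation identity, bypassing image warping.
    """
    spec.validate()
    rng_model = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[0])
    grid = spec.ct_grid
    model = _MaterialModel(spec, rng_model)
    cx, cy, cz = np.meshgrid(*(grid.axis_coords(a) for a in range(3)), indexing="ij")
    pts = np.stack([cx, cy, cz], axis=-1)
    hu_ex = model.hu(pts)
    jac = 1.0
    for axis in range(3):
        _, du = _axis_displacement(spec, axis, grid.axis_coords(axis))
        sh = [1, 1, 1]
        sh[axis] = grid.dims[axis]
        jac = jac * (1.0 + du.reshape(sh))
    hu = -1000.0 + (hu_ex + 1000.0) * (1.0 + spec.blood_shift) / jac
    return ScalarVolume(grid, hu, "HU")


def default_cohort(n: int, base_seed: int = 0, **spec_overrides) -> list[PhantomCase]:
    """Generate ``n`` phantom cases with randomized breathing effort.

    Per-case mean volume change is drawn uniformly between 8% and 40%
    (spanning shallow to deep inspiration, weighted toward sup-inf
    diaphragm motion), with a randomized sup-inf expansion gradient,
    focal-defect location/severity, and parenchymal density.  The whole
    cohort is deterministic under ``base_seed``.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    specs = cohort_specs(n, base_seed, **spec_overrides)
    return [generate_phantom(s) for s in specs]


def cohort_specs(n: int, base_seed: int = 0, **spec_overrides) -> list[PhantomSpec]:
    """The per-case :class:`PhantomSpec` list behind :func:`default_cohort`."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(base_seed)
    base = PhantomSpec(**spec_overrides) if spec_overrides else PhantomSpec()
    specs = []
    while len(specs) < n:
        # breathing effort: scale the default bump/expand pattern by a
        # factor drawn to span shallow to deep inspiration (>2-fold range
        # of percentage volume change across a cohort)
        # effort and bump-offset ranges are bounded so the displaced lung
        # always stays inside the body (validated per spec)
        effort = rng.uniform(0.45, 1.0)
        expand = tuple(effort * e for e in (0.01, 0.01, 0.05))
        bump = tuple(effort * b for b in (0.015, 0.015, 0.26))
        bump_offset = (0.0, 0.0, float(rng.uniform(-14.0, -6.0)))
        gradient = (0.0, 0.0, 0.0)
        lung = base.lung_centers_mm()[int(rng.integers(2))]
        defect_center = tuple(
            float(lung[a] + rng.uniform(-0.4, 0.4) * base.lung_semiaxes_mm[a]) for a in range(3)
        )
        deformation = DeformationSpec(
            expand=expand,
            bump=bump,
            bump_center_offset_mm=bump_offset,
            gradient=gradient,
            defect_center_mm=defect_center,
            defect_radius_mm=float(rng.uniform(8.0, 15.0)),
            defect_depth=float(rng.uniform(0.0, 0.9)),
        )
        spec = replace(
            base,
            deformation=deformation,
            parenchyma_hu_mean=float(rng.uniform(-880.0, -820.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            spec.validate()
        except SpecError:
            continue  # redraw: extreme effort/offset combination for this grid
        specs.append(spec)
    return specs
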