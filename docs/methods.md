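# Methods

## Scope and model

`ctvi-lab` implements the standard two-metric CT ventilation imaging
pipeline: deformable registration of an inhale breath-hold CT to its
exhale counterpart, followed by a Jacobian-based ventilation estimate
(local volume change) and an HU-based estimate (local air-content
change), each validated voxel-wise against a lower-resolution reference
ventilation by Spearman rank correlation. All experiments run on a
synthetic thorax phantom whose deformation is known in closed form; the
package is therefore a controlled laboratory for parameter-sensitivity
questions, not a clinical tool.

## Phantom

**Geometry.** A soft-tissue body ellipsoid (semi-axes 43 × 43 × 55 mm, 0 HU)
contains two lung ellipsoids (16 × 23 × 38 mm, centers ±17 mm left/right of
the body axis) of parenchyma at −850 ± 40 HU, threaded by 40 vessel
segments with Gaussian radial profiles (σ = 1.1 mm, peak 50 HU). Vessel
endpoints are sampled with a direction-dependent cap that keeps every
tube a fixed physical clearance inside the pleural surface: a vessel
piercing the pleura would connect the lung's above-threshold interior to
the body at strict segmentation thresholds, defeating hole-filling; the
σ and count also keep the vessel-blend volume fraction anatomically
plausible (≈ 10–15%), so the lungs survive the −600 HU end of the
threshold sweep with margin over the 50 mL component floor. The CT
grid is 96 × 96 × 64 voxels at 0.96 × 0.96 × 1.8 mm (breath-hold CT
spacing); the reference ventilation lives on a coarser grid at
2.04 × 2.04 × 2.2 mm (PET-like spacing). These are miniature lungs
(≈ 65 mL each) — the geometry scales the problem to desk size while
keeping every ratio that matters (voxel size vs. feature size vs.
deformation scale) realistic.

**Material smoothness.** All interfaces are softened: parenchymal texture
is a sum of 64 random cosine modes with wavelengths 10–40 mm (unit
variance), vessels have Gaussian cross-sections, and the pleural and skin
boundaries follow a logistic profile with 0.7 mm scale. This emulates the
scanner PSF; with hard-edged primitives, trilinear interpolation error
during warping (hundreds of HU at edges) dominates the registration
similarity and corrupts the recovered field, which no real scanner
produces.

**Deformation.** The exhale→inhale displacement is separable,
`u = (f(x), g(y), h(z))`, each component the analytic integral of

    u_a'(t) = expand_a + bump_a · exp(−(t − cb_a)² / 2w_a²)
            + gradient_a · cos(π(t − lo)/L) − defect dip,

anchored so `u = 0` at the body center. Separability gives a closed-form
Jacobian `J = (1+f′)(1+g′)(1+h′)` and exact inversion by three 1-D
monotone root-finds (dense inverse table + Newton, < 1e-6 mm). The
defaults concentrate volume change in a sup-inf Gaussian "bump"
(amplitude 0.26, width 20 mm, center 12 mm inferior), i.e. a
diaphragm-driven breath with J ranging ≈ 1.05–1.35 and a mean volume
change ≈ 20%; in-plane expansion is small (≈ 1.5–2.5%). Two properties
motivated this choice: (i) displacement stays bounded (≈ ≤ 8 mm) so the
inflated lung provably remains inside the body — `PhantomSpec.validate`
checks both diffeomorphism (1 + u′ > 0, densely sampled) and inhale
containment; (ii) the ventilation signal lives in the z-derivative,
which image registration can estimate well, while in-plane derivative
noise (whose true signal would be tiny) is kept out of the Jacobian. A
focal Gaussian defect (default depth 0.6, radius 14 mm, left lung)
provides a localized low-ventilation feature.

**Intensities.** The inhale CT is rendered analytically from the
continuous material model at the inverse-mapped coordinates with
tissue-mass conservation, `HU_in = −1000 + (HU_ex + 1000)(1+β)/J`,
where β (default 0) is an optional global blood-shift mass change.
Rendering from the continuous model rather than warping the discrete
exhale image keeps the phantom truth free of interpolation error; the
total lung mass of the two rendered phases agrees to ≈ 0.1%.
`phantom.analytic_deformed_inhale` additionally provides the exact
deformed inhale on the exhale grid (it collapses to the formula above),
used as the interpolation-free oracle for the CTVI_HU identity.

**Reference ventilation.** `(J − 1)` inside the lungs, blurred with a
mask-normalized Gaussian (FWHM 6 mm — normalization avoids diluting
boundary voxels against the zero exterior, which would scramble ranks),
linearly resampled to the coarse grid, plus Gaussian noise (σ = 0.02
ventilation units). Blur and noise set the accuracy ceiling: the true
Jacobian scores r_S ≈ 0.96 noise-free and ≈ 0.89 with default noise.
No quantitative PET PSF/noise figures exist for this setting; the values
are design choices giving a realistic, non-saturated ceiling. The
reference is rank-faithful to J − 1 by construction (no monotone
distortion), which is all Spearman validation requires.

**Cohort.** `default_cohort(n, seed)` scales the default deformation by
a per-case "effort" factor drawn U(0.45, 1.0) (volume change ≈ 9–22%,
comfortably a two-fold span), randomizes the bump center (−14…−6 mm),
defect location/size/depth, and parenchymal density (−880…−820 HU, which
also varies the air-trapping fraction). Effort and offset bounds are
chosen so every draw passes the containment check. Everything is
deterministic in the seed.

## Registration

Cubic B-spline free-form deformation on a uniform physical control
lattice, optimized per stage (default 32/16/8 mm control spacing with
4×/2×/1× image downsampling, ≤ 200 L-BFGS-B iterations each, relative
cost tolerance 1e-6). Between stages the previous field is re-fit by
separable least squares on the finer lattice. The cost is

    C = C_sim + λ · C_reg

* `C_sim`: mean squared HU difference over the union lung mask, with the
  moving image sampled trilinearly at `x + u(x)`. Gradients use
  central-difference gradient volumes of the moving image sampled at the
  displaced points (cubic sampling was measured to change accuracy by
  < 0.005 r_S at 2.5× the cost).
* `C_reg`: finite-difference bending energy (all six second derivatives,
  cross terms doubled, physical mm) plus a small amplitude term
  (1e-7 mm⁻⁴ × |u|²), averaged over the **whole domain** and scaled by
  `REG_SCALE = 3e7 HU²·mm²`. Three deliberate choices here:
  * *Global, not masked*: a regularizer restricted to the lung mask
    leaves control points near the lung surface underdetermined and
    produces spurious Jacobian structure exactly where ventilation is
    read out; integrating over the domain anchors the field, as
    production B-spline engines do.
  * *Amplitude term*: bending energy alone has an affine null space, so
    λ → ∞ would not force the field to zero; the tiny amplitude penalty
    (≈ 10⁻²·λ HU² for a 10 mm displacement at λ = 1 — negligible at the
    operating point) restores the intuitive large-λ limit.
  * *Scale*: `REG_SCALE` was calibrated once so that λ = 1 is the
    balanced operating point on default phantoms — accuracy and the
    self-correlation quality metric both peak there, folding is absent
    for λ ≥ 1, and masked MSE grows monotonically with λ. λ values are
    internally consistent but not numerically interchangeable with any
    other DIR engine's λ. One consequence: folding only appears at
    λ ≪ 0.1 here, i.e. the "folding just below λ = 1" regime of clinical
    engines corresponds to a lower λ decade in this implementation.
  Because the regularizer is a whole-domain quadratic in the
  coefficients, it is evaluated exactly on the control lattice via
  separable Gram factors (microseconds), not on the voxel grid.

The Jacobian map is computed by central differences (one-sided at
borders) of the dense displacement field in physical mm; against
closed-form separable fields the operator is accurate to ≈ 1e-4
relative at interior voxels on phantom-scale smoothness. Registrations
with any negative Jacobian inside the lungs are flagged; the sweep layer
excludes such cells from cohort means rather than silently dropping
them.

## Ventilation metrics and statistics

`CTVI_Jac = J − 1`. `CTVI_HU` uses the deformed inhale after a global
intensity correction: a single multiplicative density factor
`f = Σ_mask(HU_ex+1000) / Σ_mask(HU_in*+1000)` equalizing total masked
lung mass (the correction's published form is not fully specified; a
global mass-conserving factor is the minimal faithful reading, and a 5%
blood-shift phantom confirms it removes the induced bias to < 0.02
ventilation units). Denominators below 1 HU-equivalent are clamped and
counted. Under exact mass conservation the two metrics obey
`CTVI_HU = (J − 1)·ρ_ex` voxel-wise, which the test suite verifies to
0.01 via the analytic deformed inhale; the identity also implies the two
are rank-identical there, the basis of the self-correlation quality
metric.

Masked median smoothing takes, per lung voxel, the median over the
d×d×d index-space neighborhood restricted to lung voxels (anisotropic in
mm; 3 voxels ≙ 2.88 × 2.88 × 5.4 mm³), leaving non-lung voxels
untouched — edge-preserving in the masked sense.

Statistics go through scipy: Spearman with average-rank ties, Pearson
with Fisher-z 95% CI (`tanh(atanh r ± 1.96/√(n−3))`) and t-based
two-sided p, paired t-tests. Degenerate inputs (zero variance) return
flagged reports rather than NaN surprises.

## Sensitivity analysis

One parameter varies at a time from the baseline (−250 HU, λ = 1,
3 voxels): thresholds −600…−150 HU (10 values), λ geometrically spaced
0.05–100 (18 values; the exact published grid is unknown, so the ratio
is (100/0.05)^(1/17)), diameters {0, 3, 5, 7, 9} (0 = unfiltered
baseline). Filter sweeps reuse the baseline registration and re-smooth
only — observably equivalent and an order of magnitude cheaper. The
robust range is the maximal contiguous run containing the argmax whose
mean r_S ≥ 0.9 × the best qualifying mean with zero folding in every
included case ("within 10%" read as relative); an all-qualifying-values
variant is a one-line change in `robust_range`.

## Problem sizes and determinism

Default experiments use the 96 × 96 × 64 phantom; a full
segment-register-ventilate-validate pass takes ≈ 20–25 s on one CPU.
The test suite runs five-seed batteries at full size and scaled-down
(48 × 48 × 32, same physical extent) phantoms for unit-level checks.
All randomness flows from explicit seeds; identical seeds give
byte-identical phantoms and deterministic registrations (fixed
evaluation order, single-threaded).

## Known limitations

* The phantom has no airway tree, lobar fissures, sliding pleura, or
  PET counting physics; passing tests demonstrate correct mechanics and
  realistic parameter response, not clinical accuracy on patients.
* The mass-conservation intensity confound (inhale lungs are darker) is
  faithfully modeled, and as in real pipelines it biases MSE-driven
  registration slightly; the phantom's accuracy numbers include that
  bias.
* HU-based ventilation is noticeably noisier than Jacobian-based
  ventilation at small filter diameters — consistent with clinical
  reports — so its absolute r_S at the 3-voxel baseline is modest.
* Orientation metadata beyond spacing/origin is out of scope (phantoms
  are axis-aligned); DICOM series reading is not supported.
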