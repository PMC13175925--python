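# ctvi-lab

CT ventilation imaging (CTVI) estimates regional lung ventilation from a
pair of breath-hold CT scans instead of a nuclear-medicine scan: register
the inhale CT to the exhale CT with a deformable transform, then read the
local volume change (or air-content change) off the recovered deformation.
`ctvi-lab` is a complete, self-contained laboratory for this pipeline —
generation, validation, and parameter-sensitivity analysis — built around
a synthetic thorax phantom with exactly known ground truth, so every stage
can be tested quantitatively without patient data.

It is aimed at medical-physics researchers who want to study how CTVI
accuracy responds to algorithm parameters (segmentation threshold, DIR
regularization, smoothing) under controlled conditions.

## The pipeline

1. **Lung segmentation** — median prefilter (3 voxels), HU threshold
   (baseline −250 HU), exterior-air removal, ≥ 50 mL components, hole
   filling. The inhale ∪ exhale union mask restricts the registration
   cost to the lungs.
2. **Deformable registration** — cubic B-spline free-form deformation,
   optimized coarse-to-fine (control spacing 32 → 16 → 8 mm) by L-BFGS-B
   on
   `C(v) = C_sim(v) + λ·C_reg(v)`,
   with `C_sim` the masked mean-squared HU difference and `C_reg` the
   bending energy of the displacement plus a small amplitude penalty.
   QA follows TG-132-style metrics: % negative Jacobian determinant in
   the lungs (tissue folding ⇒ case excluded) and masked MSE decrease.
3. **Ventilation metrics** — on the exhale grid:
   `CTVI_Jac(x) = Jac(x) − 1` (fractional volume change), and
   `CTVI_HU(x) = (HU_ex − HU_in*) / (HU_in* + 1000) · ρ(x)` with
   `ρ(x) = (HU_ex(x) + 1000)/1000`, where `HU_in*` is the deformed inhale
   after a global intensity correction equalizing lung mass. Both are
   smoothed with an edge-preserving masked median filter (baseline
   3 voxels).
4. **Validation** — nearest-neighbor resampling to the reference grid and
   voxel-wise Spearman rank correlation r_S over the intersection of the
   verified and pipeline lung masks. The Spearman correlation between
   paired CTVI_Jac and CTVI_HU serves as a ground-truth-free quality
   metric.
5. **Sensitivity analysis** — one-at-a-time sweeps from the baseline
   (threshold −600…−150 HU in 50 HU steps; λ log-spaced 0.05–100 in 18
   values; filter diameters 0/3/5/7/9 voxels), with robust ranges defined
   as the contiguous run around the optimum whose mean r_S stays within
   10% of the maximum with no folding.

The phantom renders a body + two-lung ellipsoid thorax (parenchyma
≈ −850 HU with band-limited texture and vessels) deformed by a separable,
analytically invertible expansion field — so the true displacement field
and its Jacobian are known in closed form — plus a blurred, coarse, noisy
PET-like reference ventilation proportional to local volume change.

## Worked example

```python
from ctvi_lab import PhantomSpec, generate_phantom
from ctvi_lab.pipeline import run_phantom_case

case = generate_phantom(PhantomSpec(seed=1))      # 96 x 96 x 64 voxels
res = run_phantom_case(case)                      # full baseline pipeline
print(f"r_S(CTVI_Jac) = {res.r_s_jac.r:.3f}")
print(f"r_S(CTVI_HU)  = {res.r_s_hu.r:.3f}")
print(f"self-correlation = {res.self_corr.r:.3f}")
print(f"% negative Jacobian = {res.pct_neg_jac:.2f}")
```

prints (about half a minute on one CPU):

```
r_S(CTVI_Jac) = 0.889
r_S(CTVI_HU)  = 0.440
self-correlation = 0.535
% negative Jacobian = 0.00
```

i.e. the Jacobian-based map ranks ventilation nearly as well as the
phantom's noise/blur ceiling allows, the HU-based map is noisier before
heavier smoothing (its accuracy climbs from 0.28 unfiltered to 0.67 at a
9-voxel median filter on this case), the two metrics agree moderately,
and the registration is free of folding.

The numbered scripts under `analysis/` run the full study over a cohort:
`01` generates and summarizes the phantoms, `02` runs the baseline
validation, `03` performs the three parameter sweeps and reports robust
ranges, `04` correlates per-case lung volume/density factors with
accuracy, `05` evaluates the self-correlation quality metric. Outputs
land in `results/`. A thin `ctvi-lab` command-line interface exposes the
individual stages (`phantom`, `segment`, `register`, `ventilate`,
`validate`, `sweep`) for file-based use.

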