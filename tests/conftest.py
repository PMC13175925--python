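"""Shared fixtures: scaled-down phantoms for fast unit tests.

The small phantom keeps the default physical geometry (same body/lung
ellipsoids and deformation, in mm) on a grid with half the voxels per
axis, so every geometric invariant of the full-size case carries over at
an eighth of the cost.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from ctvi_lab import DeformationSpec, PhantomSpec, VolumeGrid, generate_phantom

SMALL_GRID = VolumeGrid((48, 48, 32), (1.92, 1.92, 3.6))

# moderate breathing effort and centered lungs: the 3-voxel median kernel
# spans 10.8 mm in z on this coarse grid, so the fixture needs more
# chest-wall clearance (symmetric) and avoids the deepest inspirations
SMALL_DEFORMATION = DeformationSpec(
    expand=(0.008, 0.008, 0.04), bump=(0.012, 0.012, 0.20)
)


def small_spec(**overrides) -> PhantomSpec:
    base = PhantomSpec(
        ct_grid=SMALL_GRID, deformation=SMALL_DEFORMATION, lung_sup_shift_mm=0.0
    )
    return replace(base, **overrides) if overrides else base


@pytest.fixture(scope="session")
def small_case():
    """Noisy scaled-down phantom."""
    return generate_phantom(small_spec(seed=7))


@pytest.fixture(scope="session")
def small_case_clean():
    """Noise-free scaled-down phantom."""
    return generate_phantom(small_spec(seed=7, ct_noise_sd=0.0, ref_noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
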