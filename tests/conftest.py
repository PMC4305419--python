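"""Shared fixtures: small homogeneous domains and virtual patients.

The full-scale virtual patient (18.8 cm^3 tumour on a 96^3 phantom) is
expensive to generate, so it is session-scoped and shared by every test
that needs realistic study conditions; a scaled-down patient covers
properties that are scale-free (determinism, monotonicity, bookkeeping).
"""

from __future__ import annotations

import numpy as np
import pytest

from pirtsim.anatomy import DiffusionField, TissueMap, build_diffusion_map
from pirtsim.core import CellDensityField, GrowthParams
from pirtsim.synthetic import VirtualPatientConfig, make_virtual_patient


def make_white_box(shape, voxel_size=(1.0, 1.0, 1.0)) -> TissueMap:
    """All-white-matter tissue block (homogeneous fast invasion)."""
    z = np.zeros(shape)
    return TissueMap(f_grey=z, f_white=np.ones(shape), f_csf=z.copy(),
                     voxel_size=voxel_size)


def uniform_field(shape, D_w=12.84, voxel_size=(1.0, 1.0, 1.0)) -> DiffusionField:
    return build_diffusion_map(make_white_box(shape, voxel_size), D_w)


def zero_diffusion_field(shape, voxel_size=(1.0, 1.0, 1.0)) -> DiffusionField:
    """Domain everywhere but D = 0: reaction-only dynamics."""
    return DiffusionField(
        D=np.zeros(shape), mask=np.ones(shape, dtype=bool),
        D_w=0.0, D_g=0.0, voxel_size=voxel_size,
    )


def ball_mask(shape, centre, radius_mm, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Digital ball: voxel centres within radius of a point (voxel units)."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij", sparse=True)
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, centre, voxel_size))
    return d2 <= radius_mm**2


SMALL_PATIENT_CONFIG = VirtualPatientConfig(
    shape=(48, 48, 48),
    target_t1gd_volume_cm3=4.0,
)


@pytest.fixture(scope="session")
def patient():
    """Full-scale virtual patient at the default study conditions."""
    return make_virtual_patient(seed=1)


@pytest.fixture(scope="session")
def small_patient():
    """Scaled-down virtual patient for scale-free pipeline properties."""
    return make_virtual_patient(SMALL_PATIENT_CONFIG, seed=7)
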