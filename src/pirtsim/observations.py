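"""Tumour-size observables from segmentation masks, real or simulated.

MRI-visible tumour extent is summarized by slice-summed volume
V = sum_i A_i * dz_i, the radius of the sphere of equivalent volume, and
the radial growth velocity between serial scans.  Simulated density
fields are converted to virtual MRI masks by thresholding: enhancement
on T1Gd corresponds to high cell density (default 80% of carrying
capacity) and the T2/FLAIR abnormality to low density (default 16%).
Those detection thresholds are the values used across the
proliferation-invasion glioma modelling literature, not measured for any
single scanner; every derived quantity accepts user-supplied thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "T1GD_DETECTION_FRACTION",
    "T2_DETECTION_FRACTION",
    "Observation",
    "volume_from_mask",
    "equivalent_radius",
    "velocity_from_observations",
    "virtual_mri",
]

#: Fraction of carrying capacity at which tumour enhances on T1Gd MRI.
T1GD_DETECTION_FRACTION = 0.80
#: Fraction of carrying capacity visible as T2/FLAIR abnormality.
T2_DETECTION_FRACTION = 0.16

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class Observation:
    """A dated tumour segmentation on one MRI sequence."""

    day: float
    sequence: str  # "T1Gd" | "T2"
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.sequence not in ("T1Gd", "T2"):
            raise ValueError(f"unknown MRI sequence {self.sequence!r}")
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def slice_areas_mm2(self) -> np.ndarray:
        """Tumour area A_i on each axial (z) slice."""
        pixel_area = self.voxel_size[0] * self.voxel_size[1]
        return self.mask.sum(axis=(0, 1)) * pixel_area

    @property
    def volume_cm3(self) -> float:
        v, _ = volume_from_mask(
            self.mask,
            dz_mm=self.voxel_size[2],
            pixel_area_mm2=self.voxel_size[0] * self.voxel_size[1],
        )
        return v

    @property
    def radius_mm(self) -> float:
        return equivalent_radius(self.volume_cm3)


def volume_from_mask(
    mask: np.ndarray,
    dz_mm: float | Sequence[float],
    pixel_area_mm2: float,
) -> tuple[float, np.ndarray]:
    """Slice-summed tumour volume V = sum_i A_i dz_i, in cm^3.

    ``dz_mm`` may be a scalar (uniform slice thickness) or one thickness
    per z-slice.  Also returns the per-slice areas A_i (mm^2).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (x, y, z)")
    nz = mask.shape[2]
    dz = np.broadcast_to(np.asarray(dz_mm, dtype=np.float64), (nz,))
    if np.any(dz <= 0):
        raise ValueError("slice thicknesses must be positive")
    areas = mask.sum(axis=(0, 1)) * float(pixel_area_mm2)
    volume_mm3 = float((areas * dz).sum())
    return volume_mm3 / 1000.0, areas


def equivalent_radius(volume_cm3: float) -> float:
    """Radius (mm) of the sphere with the given volume: r = (3V/4pi)^(1/3)."""
    if volume_cm3 < 0:
        raise ValueError("volume must be non-negative")
    volume_mm3 = volume_cm3 * 1000.0
    return float((3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def velocity_from_observations(obs1: Observation, obs2: Observation) -> float:
    """Radial growth velocity (cm/year) between two same-sequence scans."""
    if obs1.sequence != obs2.sequence:
        raise ValueError("velocity requires observations on the same MRI sequence")
    dt_days = obs2.day - obs1.day
    if dt_days <= 0:
        raise ValueError("observations must be ordered in time")
    dr_mm = obs2.radius_mm - obs1.radius_mm
    return dr_mm / dt_days * DAYS_PER_YEAR / 10.0  # mm/day -> cm/yr


def virtual_mri(
    density_field,
    sequence: str,
    K: float,
    thresholds: dict[str, float] | None = None,
) -> Observation:
    """Threshold a simulated density field into a virtual MRI observation.

    The mask is ``c >= theta_seq * K`` with theta defaulting to 0.80
    (T1Gd) and 0.16 (T2).
    """
    theta = {
        "T1Gd": T1GD_DETECTION_FRACTION,
        "T2": T2_DETECTION_FRACTION,
    }
    if thresholds:
        theta.update(thresholds)
    if sequence not in theta:
        raise ValueError(f"unknown MRI sequence {sequence!r}")
    mask = density_field.c >= theta[sequence] * K
    return Observation(
        day=density_field.t_days,
        sequence=sequence,
        mask=mask,
        voxel_size=density_field.voxel_size,
    )
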