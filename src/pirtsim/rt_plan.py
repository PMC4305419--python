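"""Spatio-temporal radiotherapy dose delivery dose(x, t).

A plan is a sequence of phases; each phase delivers a fixed per-fraction
dose grid on an ordered list of fraction days.  The standard glioblastoma
prescription modelled here is nested-margin conformal therapy: 54 Gy in
30 x 1.8 Gy to the T2 abnormality plus a 2.5 cm margin, then a 7.2 Gy
boost in 4 x 1.8 Gy to the T1Gd-enhancing region plus a 2 cm margin
(61.2 Gy total in the boost volume).  Dose grids are idealized step
functions (full prescription inside the dilated target, zero outside);
arbitrary grids can be loaded from NIfTI to bypass the builder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

__all__ = ["Phase", "DosePlan", "build_conformal_plan", "dilate_mask", "dose_at"]


@dataclass(frozen=True)
class Phase:
    """One treatment phase: a per-fraction dose grid and its fraction days."""

    dose_per_fraction: np.ndarray  # Gy per voxel, one fraction
    fraction_days: tuple[float, ...]

    def __post_init__(self) -> None:
        if np.any(self.dose_per_fraction < 0):
            raise ValueError("negative per-fraction dose")
        days = self.fraction_days
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("fraction days must be strictly increasing")

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_days)

    @property
    def total_dose(self) -> np.ndarray:
        return self.dose_per_fraction * self.n_fractions


@dataclass(frozen=True)
class DosePlan:
    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        days = [d for ph in self.phases for d in ph.fraction_days]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("fraction days must be strictly increasing across phases")
        shapes = {ph.dose_per_fraction.shape for ph in self.phases}
        if len(shapes) > 1:
            raise ValueError("phase dose grids differ in shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.phases[0].dose_per_fraction.shape

    @property
    def fraction_days(self) -> tuple[float, ...]:
        return tuple(d for ph in self.phases for d in ph.fraction_days)

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_days)

    def fractions(self) -> Iterator[tuple[float, np.ndarray]]:
        """Yield (day, per-fraction dose grid) in delivery order."""
        for ph in self.phases:
            for day in ph.fraction_days:
                yield day, ph.dose_per_fraction

    def cumulative_dose(self) -> np.ndarray:
        """Total physical dose (Gy) per voxel over the whole course."""
        total = np.zeros(self.shape, dtype=np.float64)
        for ph in self.phases:
            total += ph.total_dose
        return total

    def dose_at(self, t: float) -> np.ndarray:
        """Per-fraction dose grid delivered on day ``t`` (zeros if none)."""
        for day, grid in self.fractions():
            if day == t:
                return grid.copy()
        return np.zeros(self.shape, dtype=np.float64)


def dose_at(plan: DosePlan, t: float) -> np.ndarray:
    return plan.dose_at(t)


def dilate_mask(
    mask: np.ndarray,
    margin_mm: float,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Isotropic dilation of a binary mask by a physical margin (mm).

    Implemented as a Euclidean distance-transform threshold, so the
    margin is honoured on anisotropic grids.  A zero margin returns the
    mask unchanged.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=voxel_size)
    return dist <= margin_mm


def _weekday_schedule(
    start_day: float, n_fractions: int, weekdays_only: bool
) -> list[float]:
    """Daily fraction calendar; day 0 is taken to be a Monday."""
    days: list[float] = []
    d = float(start_day)
    while len(days) < n_fractions:
        if not weekdays_only or (int(round(d)) % 7) < 5:
            days.append(d)
        d += 1.0
    return days


def build_conformal_plan(
    t2_mask: np.ndarray,
    t1gd_mask: np.ndarray,
    *,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    margin_primary_mm: float = 25.0,
    margin_boost_mm: float = 20.0,
    dose_primary_gy: float = 54.0,
    n_primary: int = 30,
    dose_boost_gy: float = 7.2,
    n_boost: int = 4,
    fraction_dose_gy: float = 1.8,
    start_day: float = 0.0,
    weekdays_only: bool = True,
) -> DosePlan:
    """Two-phase nested-margin conformal plan.

    Phase 1 treats the T2 abnormality dilated by ``margin_primary_mm``;
    phase 2 boosts the T1Gd-enhancing region dilated by
    ``margin_boost_mm``, sequentially after phase 1.  Each prescription
    must divide evenly into its fractions at ``fraction_dose_gy`` per
    fraction (1.8 Gy by default: 54 = 30 x 1.8, 7.2 = 4 x 1.8).
    """
    t2_mask = np.asarray(t2_mask, dtype=bool)
    t1gd_mask = np.asarray(t1gd_mask, dtype=bool)
    if t2_mask.shape != t1gd_mask.shape:
        raise ValueError("target masks must share a grid")
    if n_primary <= 0 or n_boost < 0:
        raise ValueError("fraction counts must be positive")
    fx_primary = fx_boost = fraction_dose_gy
    for label, dose, n in (
        ("primary", dose_primary_gy, n_primary),
        ("boost", dose_boost_gy, n_boost),
    ):
        if n and abs(dose - n * fraction_dose_gy) > 1e-9 * max(dose, 1.0):
            raise ValueError(
                f"{label} dose {dose} Gy does not divide into {n} fractions "
                f"of {fraction_dose_gy} Gy"
            )

    primary_target = dilate_mask(t2_mask, margin_primary_mm, voxel_size)
    boost_target = dilate_mask(t1gd_mask, margin_boost_mm, voxel_size)

    days = _weekday_schedule(start_day, n_primary + n_boost, weekdays_only)
    phases = [
        Phase(
            dose_per_fraction=np.where(primary_target, fx_primary, 0.0),
            fraction_days=tuple(days[:n_primary]),
        )
    ]
    if n_boost:
        phases.append(
            Phase(
                dose_per_fraction=np.where(boost_target, fx_boost, 0.0),
                fraction_days=tuple(days[n_primary:]),
            )
        )
    return DosePlan(phases=tuple(phases))
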