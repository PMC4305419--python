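"""FMISO-PET hypoxia: tumour/blood images, hypoxic volumes, OER maps.

[18F]-fluoromisonidazole accumulates in hypoxic tissue; scaling the PET
activity image by the mean venous blood activity gives a tumour/blood
(T/B) ratio image.  Voxels with T/B >= 1.2 (inclusive), restricted to
the T2 abnormality plus a 2 cm margin to exclude scattered PET noise,
define the hypoxic volume (HV).  Inside the HV the radiosensitivity
parameters are divided by an oxygen enhancement ratio (OER, between 1
and 3): alpha -> alpha/OER, beta -> beta/OER^2, i.e. hypoxic voxels see
an effective dose reduced by the OER.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "HYPOXIA_TB_THRESHOLD",
    "TBImage",
    "OERMap",
    "HVResult",
    "compute_tb",
    "hypoxic_volume",
    "build_oer_map",
    "hv_report",
]

#: T/B ratio at and above which a voxel is called hypoxic.
HYPOXIA_TB_THRESHOLD = 1.2

#: Physiologic bounds on the oxygen enhancement ratio.
OER_MIN, OER_MAX = 1.0, 3.0


@dataclass(frozen=True)
class TBImage:
    """Tumour/blood FMISO ratio image with its scaling provenance."""

    values: np.ndarray
    blood_activity: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("T/B ratios must be non-negative")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class OERMap:
    """Binary spatial OER field: ``oer_value`` on the hypoxic mask, 1 elsewhere."""

    values: np.ndarray
    mask: np.ndarray
    oer_value: float
    threshold: float = HYPOXIA_TB_THRESHOLD

    def __post_init__(self) -> None:
        if not (OER_MIN <= self.oer_value <= OER_MAX):
            raise ValueError(
                f"OER must lie in [{OER_MIN}, {OER_MAX}], got {self.oer_value}"
            )


@dataclass(frozen=True)
class HVResult:
    """Hypoxic-volume measurement within a region of interest."""

    hv_cm3: float
    mask: np.ndarray
    tb_max: float | None  # None when the region is empty
    n_voxels: int


def compute_tb(
    pet_activity: np.ndarray,
    blood_activity: float,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TBImage:
    """Scale a PET activity image to a tumour/blood ratio image."""
    if blood_activity <= 0:
        raise ValueError("blood activity must be positive")
    values = np.asarray(pet_activity, dtype=np.float64) / float(blood_activity)
    return TBImage(values=values, blood_activity=float(blood_activity),
                   voxel_size=voxel_size)


def hypoxic_volume(
    tb: TBImage,
    region_mask: np.ndarray,
    threshold: float = HYPOXIA_TB_THRESHOLD,
) -> HVResult:
    """Hypoxic volume: T/B >= threshold within a region of interest.

    Returns the HV in cm^3, the hypoxic mask, and the maximum T/B inside
    the region (None for an empty region — reported missing, not an
    error).  The comparison is inclusive (>=).
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != tb.values.shape:
        raise ValueError("region mask grid does not match T/B image")
    mask = (tb.values >= threshold) & region_mask
    n = int(mask.sum())
    hv_cm3 = n * tb.voxel_volume_mm3 / 1000.0
    tb_max = float(tb.values[region_mask].max()) if region_mask.any() else None
    return HVResult(hv_cm3=hv_cm3, mask=mask, tb_max=tb_max, n_voxels=n)


def build_oer_map(
    hypoxic_mask: np.ndarray,
    oer_value: float,
    threshold: float = HYPOXIA_TB_THRESHOLD,
) -> OERMap:
    """Binary OER field: ``oer_value`` inside the hypoxic mask, 1 outside.

    ``oer_value = 1`` gives the identity map (spatially uniform
    radiosensitivity scenario).
    """
    hypoxic_mask = np.asarray(hypoxic_mask, dtype=bool)
    if not (OER_MIN <= oer_value <= OER_MAX):
        raise ValueError(f"OER must lie in [{OER_MIN}, {OER_MAX}], got {oer_value}")
    values = np.where(hypoxic_mask, float(oer_value), 1.0)
    return OERMap(values=values, mask=hypoxic_mask, oer_value=float(oer_value),
                  threshold=threshold)


def hv_report(
    tb: TBImage,
    regions: Mapping[str, np.ndarray],
    threshold: float = HYPOXIA_TB_THRESHOLD,
):
    """Regional HV accounting table: one row per region of interest.

    Returns a DataFrame with columns ``region``, ``hv_cm3``, ``tb_max``,
    mirroring the usual regional breakdown (T2 + 2 cm margin, T2 less
    T1Gd, T1Gd core).
    """
    import pandas as pd

    rows = []
    for name, mask in regions.items():
        res = hypoxic_volume(tb, mask, threshold)
        rows.append({"region": name, "hv_cm3": res.hv_cm3, "tb_max": res.tb_max})
    return pd.DataFrame(rows)
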