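"""Brain tissue phantoms and the spatially varying diffusion field.

The brain is represented as per-voxel grey / white / CSF fractions on a
regular grid (a BrainWeb-style fuzzy phantom).  Glioma cells migrate along
white-matter tracts roughly two orders of magnitude faster than through
grey matter, and CSF acts as an impermeable barrier, so the tissue
composition fixes both the local invasion rate D(x) and the domain on
which the growth PDE is solved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TissueMap", "DiffusionField", "build_diffusion_map"]

#: White-to-grey motility ratio: glioma cells migrate ~100x faster in
#: myelinated white matter than in dense grey matter.
WHITE_GREY_MOTILITY_RATIO = 100.0

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class TissueMap:
    """Per-voxel grey/white/CSF composition on a regular 3D grid.

    Fractions are in ``[0, 1]`` and may sum to less than one; the
    remainder is background (outside the head).  Voxel size is in mm.
    """

    f_grey: np.ndarray
    f_white: np.ndarray
    f_csf: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {self.f_grey.shape, self.f_white.shape, self.f_csf.shape}
        if len(shapes) != 1:
            raise ValueError(f"tissue fraction arrays differ in shape: {shapes}")
        if self.f_grey.ndim != 3:
            raise ValueError("tissue fractions must be 3D arrays")
        for name in ("f_grey", "f_white", "f_csf"):
            f = getattr(self, name)
            if np.any(f < -_FRACTION_TOL) or np.any(f > 1 + _FRACTION_TOL):
                raise ValueError(f"{name} outside [0, 1]")
        total = self.f_grey + self.f_white + self.f_csf
        if np.any(total > 1 + 1e-3):
            raise ValueError(
                f"tissue fractions sum to {total.max():.4f} > 1 at some voxel"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.f_grey.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def brain_mask(self) -> np.ndarray:
        """Voxels containing any tissue (grey, white or CSF)."""
        return (self.f_grey + self.f_white + self.f_csf) > _FRACTION_TOL

    @classmethod
    def from_nifti(cls, grey_path, white_path, csf_path) -> "TissueMap":
        """Load a phantom from three single-class NIfTI probability maps."""
        import nibabel as nib

        imgs = [nib.load(str(p)) for p in (grey_path, white_path, csf_path)]
        zooms = imgs[0].header.get_zooms()[:3]
        arrays = [np.asarray(img.get_fdata(), dtype=np.float64) for img in imgs]
        return cls(*arrays, voxel_size=tuple(float(z) for z in zooms))

    def to_nifti(self, grey_path, white_path, csf_path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_size) + [1.0])
        for arr, path in zip(
            (self.f_grey, self.f_white, self.f_csf),
            (grey_path, white_path, csf_path),
        ):
            nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))


@dataclass(frozen=True)
class DiffusionField:
    """Voxel-wise net invasion rate D(x) and the simulation domain.

    ``D`` is in mm^2 per year; ``mask`` marks voxels where tumour cells
    may exist (grey/white dominated).  D is zero off-domain so CSF and
    background behave as no-flux obstacles.
    """

    D: np.ndarray
    mask: np.ndarray
    D_w: float
    D_g: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.D.shape != self.mask.shape:
            raise ValueError("D and mask shapes differ")
        if np.any(self.D < 0):
            raise ValueError("negative diffusion rate")
        if np.any(self.D[~self.mask] != 0):
            raise ValueError("D must vanish outside the domain mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.D.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


def build_diffusion_map(
    tissue: TissueMap,
    D_w: float,
    *,
    d_is_white: bool = True,
    domain_threshold: float = 0.5,
) -> DiffusionField:
    """Construct D(x) from a tissue phantom and a white-matter motility rate.

    Partial-volume voxels get a linear blend
    ``D = D_w * f_white + D_g * f_grey`` with ``D_g = D_w / 100``.  Voxels
    with ``f_grey + f_white <= domain_threshold`` (CSF, background) are
    excluded from the domain and carry ``D = 0``.

    Parameters
    ----------
    D_w:
        Net invasion rate in mm^2/year.  Interpreted as the white-matter
        rate when ``d_is_white`` (default); when ``d_is_white=False`` it is
        taken as the grey-matter rate and the white rate becomes 100x it.
        Patient-level invasion rates reported from serial imaging do not
        always state which tissue they refer to, hence the flag.
    """
    if D_w <= 0:
        raise ValueError(f"motility rate must be positive, got {D_w}")
    if d_is_white:
        white_rate = float(D_w)
    else:
        white_rate = float(D_w) * WHITE_GREY_MOTILITY_RATIO
    grey_rate = white_rate / WHITE_GREY_MOTILITY_RATIO

    mask = (tissue.f_grey + tissue.f_white) > domain_threshold
    if not mask.any():
        raise ValueError("empty simulation domain: no grey/white dominated voxels")
    D = white_rate * tissue.f_white + grey_rate * tissue.f_grey
    D = np.where(mask, D, 0.0)
    return DiffusionField(
        D=D, mask=mask, D_w=white_rate, D_g=grey_rate, voxel_size=tissue.voxel_size
    )
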