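"""Model-data agreement: voxel-wise similarity, radius errors, surface distances.

Confusion-matrix metrics (PPV, sensitivity, specificity, Jaccard, volume
similarity) are computed inside an evaluation region — by default the
union of both masks dilated by 2 cm — because counting true negatives
over the whole head inflates specificity meaninglessly.  Morphological
agreement is summarized by the signed distance from each predicted
surface voxel to the observed surface (positive outside the observed
mask = over-estimation, negative inside = under-estimation); exact
surface intersections (distance zero) are tallied separately and
excluded from the median/SD so they cannot mask bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from pirtsim.observations import Observation
from pirtsim.rt_plan import dilate_mask

__all__ = [
    "SimilarityReport",
    "SurfaceDistanceResult",
    "confusion_metrics",
    "radius_errors",
    "surface_voxels",
    "surface_distance",
]


@dataclass(frozen=True)
class SimilarityReport:
    """Voxel-wise agreement between a predicted and an observed mask.

    Ratio metrics are ``None`` when their denominator is zero
    (undefined, not zero).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    ppv: float | None
    sensitivity: float | None
    specificity: float | None
    jaccard: float | None
    volume_similarity: float | None

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "PPV": self.ppv, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "jaccard": self.jaccard,
            "volume_similarity": self.volume_similarity,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_metrics(
    pred_mask: np.ndarray,
    obs_mask: np.ndarray,
    eval_region: np.ndarray | None = None,
    *,
    voxel_size=(1.0, 1.0, 1.0),
    region_margin_mm: float = 20.0,
) -> SimilarityReport:
    """Voxel-wise similarity metrics within an evaluation region.

    PPV = TP/(TP+FP), sensitivity = TP/(TP+FN), specificity = TN/(FP+TN),
    Jaccard = TP/(FN+TP+FP), volume similarity = 1 - |FP-FN|/(FP+2TP+FN).
    When ``eval_region`` is omitted it defaults to the union of the two
    masks dilated by ``region_margin_mm``.
    """
    pred = np.asarray(pred_mask, dtype=bool)
    obs = np.asarray(obs_mask, dtype=bool)
    if pred.shape != obs.shape:
        raise ValueError("masks must share a grid")
    if eval_region is None:
        eval_region = dilate_mask(pred | obs, region_margin_mm, voxel_size)
    else:
        eval_region = np.asarray(eval_region, dtype=bool)
        if eval_region.shape != pred.shape:
            raise ValueError("evaluation region grid does not match masks")
    if not eval_region.any():
        raise ValueError("evaluation region is empty")

    p, o = pred[eval_region], obs[eval_region]
    tp = int(np.count_nonzero(p & o))
    fp = int(np.count_nonzero(p & ~o))
    fn = int(np.count_nonzero(~p & o))
    tn = int(np.count_nonzero(~p & ~o))
    return SimilarityReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        ppv=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, fp + tn),
        jaccard=_ratio(tp, fn + tp + fp),
        volume_similarity=(
            1.0 - abs(fp - fn) / (fp + 2 * tp + fn) if (fp + 2 * tp + fn) else None
        ),
    )


def radius_errors(
    pred_obs: Observation, true_obs: Observation
) -> tuple[float | None, float]:
    """(relative %, absolute mm) error between equivalent spherical radii."""
    if pred_obs.sequence != true_obs.sequence:
        raise ValueError("radius errors compare observations of the same sequence")
    r_pred, r_obs = pred_obs.radius_mm, true_obs.radius_mm
    absolute = abs(r_pred - r_obs)
    relative = 100.0 * absolute / r_obs if r_obs > 0 else None
    return relative, absolute


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Digital surface: mask voxels with >= 1 six-connected background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


@dataclass(frozen=True)
class SurfaceDistanceResult:
    """Signed distances from predicted to observed tumour surface (mm).

    ``distances`` excludes exact intersections (distance 0), which are
    counted in ``zero_count``; ``median``/``sd`` are over the nonzero
    sample (0 when every surface voxel intersects).
    """

    distances: np.ndarray
    median: float
    sd: float
    zero_count: int

    @property
    def n(self) -> int:
        return self.distances.size + self.zero_count


def surface_distance(
    pred_mask: np.ndarray,
    obs_mask: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
    *,
    symmetric: bool = False,
) -> SurfaceDistanceResult:
    """Signed Euclidean distance distribution between tumour surfaces.

    For each predicted-surface voxel, the distance to the nearest
    observed-surface voxel (voxel centre to voxel centre), signed
    positive when the predicted voxel lies outside the observed mask
    (model over-estimates the front) and negative inside.  With
    ``symmetric=True`` the observed-to-predicted distances are pooled in
    as well (with the same sign convention relative to the observed
    mask).
    """
    pred = np.asarray(pred_mask, dtype=bool)
    obs = np.asarray(obs_mask, dtype=bool)
    if pred.shape != obs.shape:
        raise ValueError("masks must share a grid")
    if not pred.any() or not obs.any():
        raise ValueError("surface distance requires two non-empty masks")

    def directed(a: np.ndarray, b: np.ndarray, inside: np.ndarray) -> np.ndarray:
        surf_a, surf_b = surface_voxels(a), surface_voxels(b)
        dist_to_b = ndimage.distance_transform_edt(~surf_b, sampling=voxel_size)
        d = dist_to_b[surf_a]
        sign = np.where(inside[surf_a], -1.0, 1.0)
        return sign * d

    sample = directed(pred, obs, obs)
    if symmetric:
        # observed surface measured against the predicted one; sign keeps
        # the over/under-estimation semantics: an observed-surface voxel
        # swallowed by the predicted mask means the model front lies
        # beyond it (over-estimate, positive)
        surf_obs = surface_voxels(obs)
        dist_to_pred = ndimage.distance_transform_edt(
            ~surface_voxels(pred), sampling=voxel_size
        )
        d = dist_to_pred[surf_obs]
        sign = np.where(pred[surf_obs], 1.0, -1.0)
        sample = np.concatenate([sample, sign * d])

    zero_count = int(np.count_nonzero(sample == 0))
    nonzero = sample[sample != 0]
    if nonzero.size:
        median = float(np.median(nonzero))
        sd = float(np.std(nonzero, ddof=0))
    else:
        median, sd = 0.0, 0.0
    return SurfaceDistanceResult(
        distances=nonzero, median=median, sd=sd, zero_count=zero_count
    )
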