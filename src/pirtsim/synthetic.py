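"""Synthetic inputs: brain phantoms, FMISO T/B maps, whole virtual patients.

Every generator is a pure function of (config, seed), so the entire
pipeline — growth, planning, hypoxia mapping, treatment, calibration —
can be exercised end-to-end without any imaging data.

The virtual patient emulates the clinical history of a newly diagnosed
glioblastoma: two pre-treatment MRIs 13 days apart with a
contrast-enhancing volume near 18.8 cm^3 at the second scan, an FMISO
T/B image whose background matches the observed whole-brain statistics
(mean 0.813, SD 0.223, right-skewed) with a focal hypoxic region
straddling the dense core and invasive edge, a nested-margin
chemoradiation plan (54 Gy / 30 fx to T2 + 2.5 cm, 7.2 Gy / 4 fx boost
to T1Gd + 2 cm), and a post-treatment MRI 3 days after the last
fraction.  Ground-truth growth and response parameters default to the
mid-range glioblastoma kinetics D = 12.84 mm^2/yr, rho = 13.82 /yr,
alpha = 0.055 /Gy.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from pirtsim.anatomy import DiffusionField, TissueMap, build_diffusion_map
from pirtsim.core import (
    CellDensityField,
    GrowthParams,
    Integrator,
    RadiosensitivityParams,
    simulate,
)
from pirtsim.hypoxia import (
    HYPOXIA_TB_THRESHOLD,
    OERMap,
    TBImage,
    build_oer_map,
    hypoxic_volume,
)
from pirtsim.observations import Observation, virtual_mri
from pirtsim.rt_plan import DosePlan, build_conformal_plan, dilate_mask

__all__ = [
    "make_phantom",
    "truncated_lognormal_params",
    "make_tb_map",
    "VirtualPatientConfig",
    "VirtualPatient",
    "make_virtual_patient",
]


def _ellipsoid_level(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    centre_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
) -> np.ndarray:
    """Normalized ellipsoid radius: < 1 inside, 1 on the surface."""
    x, y, z = coords
    return np.sqrt(
        ((x - centre_mm[0]) / semi_axes_mm[0]) ** 2
        + ((y - centre_mm[1]) / semi_axes_mm[1]) ** 2
        + ((z - centre_mm[2]) / semi_axes_mm[2]) ** 2
    )


def _soft_inside(level: np.ndarray, scale_mm: float, blend_mm: float) -> np.ndarray:
    """Fractional membership with a linear ramp ~``blend_mm`` wide."""
    signed_dist = (1.0 - level) * scale_mm
    return np.clip(signed_dist / blend_mm + 0.5, 0.0, 1.0)


def make_phantom(
    shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    cortex_thickness_mm: float = 3.0,
    ventricle_semi_axes_mm: tuple[float, float, float] = (16.0, 5.0, 7.0),
    blend_mm: float = 1.0,
    seed: int | None = None,
) -> TissueMap:
    """Layered ellipsoidal head phantom with fuzzy tissue fractions.

    An outer grey-matter cortical shell wraps a white-matter interior;
    two elongated CSF ventricles sit off-centre.  Interfaces are blended
    over ~1 mm so partial-volume voxels occur as in a fuzzy
    tissue-probability atlas.  The geometry is deterministic; ``seed`` is
    accepted for interface uniformity with the stochastic generators.
    """
    if min(shape) < 16:
        raise ValueError("phantom needs at least 16 voxels per axis")
    extent = [n * v for n, v in zip(shape, voxel_size)]
    centre = [e / 2.0 for e in extent]
    head_axes = [0.46 * e for e in extent]
    if min(head_axes) < cortex_thickness_mm + 2 * blend_mm + 2.0:
        raise ValueError("phantom too small to contain cortex and interior")

    axes_mm = [
        (np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)
    ]
    coords = np.meshgrid(*axes_mm, indexing="ij", sparse=True)

    head_level = _ellipsoid_level(coords, centre, head_axes)
    scale = min(head_axes)
    head = _soft_inside(head_level, scale, blend_mm)
    # fraction of the head interior deeper than the cortical shell
    interior_level = head_level * scale / (scale - cortex_thickness_mm)
    interior = _soft_inside(interior_level, scale - cortex_thickness_mm, blend_mm)

    vent = np.zeros(shape)
    for dy in (-8.0, 8.0):
        v_centre = (centre[0] - 8.0, centre[1] + dy, centre[2] + 2.0)
        level = _ellipsoid_level(coords, v_centre, ventricle_semi_axes_mm)
        vent = np.maximum(
            vent, _soft_inside(level, min(ventricle_semi_axes_mm), blend_mm)
        )

    f_csf = head * vent
    f_white = head * interior * (1.0 - vent)
    f_grey = head * (1.0 - interior) * (1.0 - vent)
    return TissueMap(
        f_grey=f_grey, f_white=f_white, f_csf=f_csf, voxel_size=voxel_size
    )


def default_seed_voxel(tissue: TissueMap, offset_mm: float = 18.0) -> tuple[int, int, int]:
    """A deep-white-matter voxel displaced from the phantom centre.

    Mimics a tumour centred in the hemispheric white matter, clear of the
    ventricles (which sit on the -x side of the default phantom).
    """
    centre_vox = [n // 2 for n in tissue.shape]
    i = centre_vox[0] + int(round(offset_mm / tissue.voxel_size[0]))
    loc = (i, centre_vox[1], centre_vox[2])
    if tissue.f_white[loc] <= 0.5:
        raise ValueError("default seed location is not white-dominant; pass one")
    return loc


def truncated_lognormal_params(
    mean: float, sd: float, upper: float
) -> tuple[float, float]:
    """(mu, sigma) of a lognormal whose truncation to (0, upper) has the
    requested mean and SD.

    Uses the closed-form partial moments
    E[X^k 1{X<a}] = exp(k mu + k^2 sigma^2 / 2) Phi((ln a - mu - k sigma^2)/sigma).
    """
    if not (0 < mean < upper):
        raise ValueError("need 0 < mean < upper truncation bound")

    log_a = math.log(upper)

    def moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        z0 = (log_a - mu) / sigma
        z1 = (log_a - mu - sigma**2) / sigma
        z2 = (log_a - mu - 2 * sigma**2) / sigma
        p0 = stats.norm.cdf(z0)
        m1 = math.exp(mu + sigma**2 / 2) * stats.norm.cdf(z1) / p0
        m2 = math.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf(z2) / p0
        var = m2 - m1**2
        return m1 - mean, math.sqrt(max(var, 1e-300)) - sd

    # start from the untruncated moment match
    sigma0 = math.sqrt(math.log(1 + (sd / mean) ** 2))
    mu0 = math.log(mean) - sigma0**2 / 2
    sol = optimize.root(moments, x0=[mu0, math.log(sigma0)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated lognormal moment match failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def make_tb_map(
    tissue: TissueMap,
    tumour_mask: np.ndarray,
    *,
    background_mean: float = 0.813,
    background_sd: float = 0.223,
    focus_level: float = 1.5,
    focus_fraction: float = 0.13,
    threshold: float = HYPOXIA_TB_THRESHOLD,
    blood_activity: float = 1.0,
    seed: int | None = 0,
) -> TBImage:
    """Synthetic FMISO tumour/blood ratio image.

    Background T/B over brain voxels is right-skewed lognormal noise
    whose moments, after truncation below the hypoxia threshold, match
    the requested whole-brain mean/SD — truncation keeps stray
    suprathreshold background voxels from contaminating the hypoxic
    volume, which in real images is controlled by restricting the signal
    to the tumour region.  A contiguous focal region at ``focus_level``
    covering ``focus_fraction`` of the tumour mask is grown around a
    point on the tumour surface, so the hypoxic volume spans both the
    bulk mass and the invasive edge.
    """
    if not (0 <= focus_fraction <= 1):
        raise ValueError("focus fraction must lie in [0, 1]")
    tumour_mask = np.asarray(tumour_mask, dtype=bool)
    if tumour_mask.shape != tissue.shape:
        raise ValueError("tumour mask grid does not match phantom")
    if focus_fraction > 0 and not tumour_mask.any():
        raise ValueError("cannot place a hypoxic focus in an empty tumour mask")
    if focus_fraction > 0 and focus_level < threshold:
        raise ValueError("focus T/B level below the hypoxia threshold")

    rng = np.random.default_rng(seed)
    brain = tissue.brain_mask
    values = np.zeros(tissue.shape, dtype=np.float64)

    mu, sigma = truncated_lognormal_params(background_mean, background_sd, threshold)
    n_brain = int(brain.sum())
    draws = rng.lognormal(mean=mu, sigma=sigma, size=n_brain)
    bad = draws >= threshold
    while bad.any():  # rejection resampling of the truncated tail
        draws[bad] = rng.lognormal(mean=mu, sigma=sigma, size=int(bad.sum()))
        bad = draws >= threshold
    values[brain] = draws

    if focus_fraction > 0:
        n_target = max(1, int(round(focus_fraction * tumour_mask.sum())))
        centre = _tumour_surface_point(tumour_mask, tissue.voxel_size)
        idx = np.argwhere(brain)
        pos = (idx + 0.5) * np.asarray(tissue.voxel_size)
        d2 = ((pos - centre) ** 2).sum(axis=1)
        if n_target > idx.shape[0]:
            raise ValueError("hypoxic focus larger than the brain")
        order = np.argsort(d2, kind="stable")[:n_target]
        chosen = idx[order]
        values[tuple(chosen.T)] = focus_level

    return TBImage(
        values=values, blood_activity=blood_activity, voxel_size=tissue.voxel_size
    )


def _tumour_surface_point(
    tumour_mask: np.ndarray, voxel_size: Sequence[float]
) -> np.ndarray:
    """Deterministic point (mm) on the tumour surface: the boundary voxel
    farthest along +x, mimicking a hypoxic focus at the core/edge interface."""
    from pirtsim.metrics import surface_voxels

    surf = np.argwhere(surface_voxels(tumour_mask))
    best = surf[np.lexsort((surf[:, 2], surf[:, 1], surf[:, 0]))][-1]
    return (best + 0.5) * np.asarray(voxel_size)


@dataclass(frozen=True)
class VirtualPatientConfig:
    """Ground truth and acquisition schedule for a virtual patient."""

    D_mm2_per_year: float = 12.84
    rho_per_year: float = 13.82
    alpha_per_gy: float = 0.055
    alpha_beta_gy: float = 10.0
    oer: float = 2.5
    target_t1gd_volume_cm3: float = 18.8
    pre_interval_days: float = 13.0
    rt_start_delay_days: float = 5.0
    post_rt_mri_delay_days: float = 3.0
    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed_density_fraction: float = 0.8
    seed_location: tuple[int, int, int] | None = None
    focus_level: float = 1.5
    focus_fraction: float = 0.13
    tb_background_mean: float = 0.813
    tb_background_sd: float = 0.223
    hv_region_margin_mm: float = 20.0
    margin_primary_mm: float = 25.0
    margin_boost_mm: float = 20.0
    max_growth_days: float = 3000.0


@dataclass
class VirtualPatient:
    """A complete synthetic patient: ground truth plus everything the
    pipeline would normally read from images."""

    config: VirtualPatientConfig
    seed: int | None
    tissue: TissueMap
    diffusion: DiffusionField
    growth: GrowthParams
    rt_params: RadiosensitivityParams
    tb: TBImage
    hypoxic_mask: np.ndarray
    oer_map: OERMap
    plan: DosePlan
    pre_obs: dict[tuple[int, str], Observation]  # (visit 1|2, sequence)
    pre_rt_density: CellDensityField
    post_obs: dict[str, Observation]
    post_rt_density: CellDensityField
    post_mri_day: float

    @property
    def ground_truth(self) -> dict:
        c = self.config
        return {
            "D_mm2_per_year": c.D_mm2_per_year,
            "rho_per_year": c.rho_per_year,
            "alpha_per_gy": c.alpha_per_gy,
            "oer": c.oer,
        }


def _grow_to_volume(
    diffusion: DiffusionField,
    growth: GrowthParams,
    config: VirtualPatientConfig,
) -> tuple[CellDensityField, CellDensityField]:
    """Grow a single-voxel seed until the virtual T1Gd volume reaches the
    target; return the states at (target - pre_interval) and at target."""
    from pirtsim.core import seed_initial_condition

    loc = config.seed_location
    if loc is None:
        centre = [n // 2 for n in diffusion.shape]
        loc = (
            centre[0] + int(round(18.0 / diffusion.voxel_size[0])),
            centre[1],
            centre[2],
        )
    init = seed_initial_condition(
        diffusion, loc, config.seed_density_fraction * growth.K, growth.K
    )
    integ = Integrator(diffusion, growth, init)

    def t1gd_volume() -> float:
        return virtual_mri(integ.snapshot(), "T1Gd", growth.K).volume_cm3

    # coarse march until close to the target, then daily chunks so the
    # crossing (and hence the second-visit volume) lands within ~1% of it;
    # a rolling history provides the state exactly pre_interval earlier
    coarse = config.pre_interval_days / 2.0
    fine = 1.0
    n_back = int(round(config.pre_interval_days / fine))
    # switch to fine chunks well before the target so the rolling history
    # spans a full inter-visit interval by the time the volume crosses
    while integ.t < config.max_growth_days and t1gd_volume() < 0.4 * config.target_t1gd_volume_cm3:
        integ.advance(integ.t + coarse)
    history: deque[CellDensityField] = deque(maxlen=n_back + 1)
    history.append(integ.snapshot())
    while integ.t < config.max_growth_days:
        integ.advance(integ.t + fine)
        history.append(integ.snapshot())
        if t1gd_volume() >= config.target_t1gd_volume_cm3:
            if len(history) < n_back + 1:
                raise RuntimeError(
                    "target volume reached before the first virtual MRI date"
                )
            return history[0], history[-1]
    raise RuntimeError(
        f"target T1Gd volume {config.target_t1gd_volume_cm3} cm^3 not reached "
        f"within {config.max_growth_days} days"
    )


def make_virtual_patient(
    config: VirtualPatientConfig | None = None, seed: int | None = 0
) -> VirtualPatient:
    """Generate a complete virtual glioblastoma patient.

    Grows a tumour under the ground-truth kinetics until the virtual
    contrast-enhancing volume reaches the target, records two
    pre-treatment MRI visits ``pre_interval_days`` apart, synthesizes the
    FMISO T/B image and hypoxic volume, builds the nested-margin plan
    starting ``rt_start_delay_days`` after the second visit, simulates
    chemoradiation under the ground-truth OER, and records the
    post-treatment MRI.  Identical (config, seed) give identical output.
    """
    config = config or VirtualPatientConfig()
    tissue = make_phantom(shape=config.shape, voxel_size=config.voxel_size)
    diffusion = build_diffusion_map(tissue, config.D_mm2_per_year)
    growth = GrowthParams(D_w=config.D_mm2_per_year, rho=config.rho_per_year)
    rt_params = RadiosensitivityParams(
        alpha=config.alpha_per_gy, alpha_beta_ratio=config.alpha_beta_gy
    )

    state1, state2 = _grow_to_volume(diffusion, growth, config)
    pre_obs = {
        (1, "T1Gd"): virtual_mri(state1, "T1Gd", growth.K),
        (1, "T2"): virtual_mri(state1, "T2", growth.K),
        (2, "T1Gd"): virtual_mri(state2, "T1Gd", growth.K),
        (2, "T2"): virtual_mri(state2, "T2", growth.K),
    }

    t1gd_mask = pre_obs[(2, "T1Gd")].mask
    t2_mask = pre_obs[(2, "T2")].mask
    plan = build_conformal_plan(
        t2_mask,
        t1gd_mask,
        voxel_size=config.voxel_size,
        margin_primary_mm=config.margin_primary_mm,
        margin_boost_mm=config.margin_boost_mm,
        start_day=state2.t_days + config.rt_start_delay_days,
    )

    tb = make_tb_map(
        tissue,
        t1gd_mask,
        background_mean=config.tb_background_mean,
        background_sd=config.tb_background_sd,
        focus_level=config.focus_level,
        focus_fraction=config.focus_fraction,
        seed=seed,
    )
    hv_region = dilate_mask(t2_mask, config.hv_region_margin_mm, config.voxel_size)
    hv = hypoxic_volume(tb, hv_region)
    oer_map = build_oer_map(hv.mask, config.oer)

    post_mri_day = plan.fraction_days[-1] + config.post_rt_mri_delay_days
    result = simulate(
        diffusion,
        growth,
        state2,
        post_mri_day - state2.t_days,
        plan=plan,
        oer_map=oer_map,
        rt_params=rt_params,
    )
    post_state = result.final
    post_obs = {
        "T1Gd": virtual_mri(post_state, "T1Gd", growth.K),
        "T2": virtual_mri(post_state, "T2", growth.K),
    }

    return VirtualPatient(
        config=config,
        seed=seed,
        tissue=tissue,
        diffusion=diffusion,
        growth=growth,
        rt_params=rt_params,
        tb=tb,
        hypoxic_mask=hv.mask,
        oer_map=oer_map,
        plan=plan,
        pre_obs=pre_obs,
        pre_rt_density=state2,
        post_obs=post_obs,
        post_rt_density=post_state,
        post_mri_day=post_mri_day,
    )
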