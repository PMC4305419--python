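# pirtsim

Patient-specific modelling of glioblastoma growth and radiotherapy
response with hypoxia-mediated radiation resistance.

Glioblastoma is a diffusely invasive brain tumour: the cells visible on
MRI are only the dense core of a gradient of infiltration that extends
far beyond any imageable margin, and hypoxic sub-regions of the tumour —
identifiable on [¹⁸F]-fluoromisonidazole (FMISO) PET — are substantially
more resistant to radiation than well-oxygenated tissue.  `pirtsim`
implements the proliferation–invasion radiotherapy (PIRT) model, which
ties these observations together in a single mechanistic simulation that
can be calibrated to an individual patient from routine imaging, and
asks: how much of the observed response to chemoradiation is explained
by hypoxic radioprotection?

## The model

Tumour cell density *c*(**x**, *t*) (cells/mm³) evolves by
reaction–diffusion with a radiotherapy loss term:

    ∂c/∂t = ∇·(D(x) ∇c) + ρ c (1 − c/K) − R(x, t, c)

- **D(x)** — net invasion rate (mm²/yr), built from a grey/white/CSF
  tissue phantom: cells migrate 100× faster in white matter than grey
  (D_w = 100 D_g), and CSF is a no-flux barrier.
- **ρ** — net proliferation rate (1/yr); logistic growth saturates at
  the carrying capacity K = 1/((4/3)π(d/2)³) ≈ 1.91 × 10⁶ cells/mm³ for
  10 µm cells.
- **R** — at each treatment fraction, an instantaneous density-dependent
  kill c → c − (1 − S)·c·(1 − c/K), with the linear-quadratic surviving
  fraction S = exp(−α d − β d²), α/β fixed at 10 Gy.  At c = K (necrotic
  core) there is no radiographic response.
- **Hypoxia** — inside the hypoxic volume (FMISO tumour/blood ratio
  ≥ 1.2 within the T2 abnormality + 2 cm), the radiosensitivity is
  reduced by an oxygen enhancement ratio: α → α/OER, β → β/OER², with
  OER ∈ [1, 3].

Patient-specific parameters come from imaging alone: the Fisher front
velocity v = 2√(Dρ) measured from serial T1Gd volumes, the infiltration
length λ = √(D/ρ) from the T2–T1Gd radius gap (the "invisibility index"
D/ρ = λ² measures imaging-occult disease), and α from a bracketed
monotone fit to the first post-treatment T2 tumour size.

Because no patient images ship with the package, a first-class synthetic
module generates complete **virtual patients** — layered brain phantom,
serial pre-treatment MRI, FMISO T/B map with realistic background
statistics (0.813 ± 0.223, right-skewed), a nested-margin conformal
plan (54 Gy/30 fx to T2 + 2.5 cm, 7.2 Gy/4 fx boost to T1Gd + 2 cm), and
simulated post-treatment imaging — with known ground truth, so every
stage of the pipeline is testable end-to-end.

## Worked example

Generate a virtual patient with known kinetics (D = 12.84 mm²/yr,
ρ = 13.82 /yr, α = 0.055 /Gy, OER = 2.5), then recover those parameters
from its synthetic imaging alone:

```python
from pirtsim.synthetic import make_virtual_patient
from pirtsim.calibration import estimate_from_observations, calibrate_alpha
from pirtsim.pipeline import post_rt_radius, oer_sweep

patient = make_virtual_patient(seed=1)
obs = patient.pre_obs

est = estimate_from_observations(obs[(1, "T1Gd")], obs[(2, "T1Gd")], obs[(2, "T2")])
print(f"D = {est.D_mm2_per_year:.2f} mm^2/yr   rho = {est.rho_per_year:.2f} /yr   "
      f"D/rho = {est.invisibility_index_mm2:.2f} mm^2   v = {est.velocity_cm_per_year:.2f} cm/yr")

fit = calibrate_alpha(
    lambda a: post_rt_radius(patient, a, sequence="T2", oer_value=patient.config.oer),
    patient.post_obs["T2"].radius_mm,
)
print(f"alpha = {fit.alpha:.4f} /Gy")

table, argmin = oer_sweep(patient, [1.0, 1.5, 2.0, 2.5, 3.0])
print(table.to_string(index=False))
print(f"minimum model-data error at OER = {argmin:g}")
```

This prints:

```
D = 12.50 mm^2/yr   rho = 13.77 /yr   D/rho = 0.91 mm^2   v = 2.62 cm/yr
alpha = 0.0550 /Gy
 oer  relative_radius_error_pct
 1.0                   3.645486
 1.5                   1.808184
 2.0                   0.677691
 2.5                   0.000000
 3.0                   0.448105
minimum model-data error at OER = 2.5
```

The growth rates are recovered within a few percent of the generating
values (the residual is voxelization plus the finite-time approach to
the Fisher travelling wave), the radiosensitivity fit is essentially
exact, and the sweep of relative volumetric error over OER values is
convex with its minimum at the ground-truth OER — simulations that
ignore hypoxic protection (OER = 1) misplace the post-treatment tumour
front.

The same stages are available from a shell via the `pirtsim` CLI
(`synth`, `simulate`, `calibrate`, `scenarios`, `sweep`, `metrics`),
with YAML configs, NIfTI rasters and CSV/JSON reports.

## Layout

- `pirtsim.anatomy` — tissue phantoms, diffusion field D(x)
- `pirtsim.core` — the PDE solver (Strang splitting, LQ fraction kill)
- `pirtsim.rt_plan` — dose grids and fraction schedules
- `pirtsim.hypoxia` — T/B images, hypoxic volume, OER maps
- `pirtsim.observations` — volumes, radii, velocities, virtual MRI
- `pirtsim.calibration` — (D, ρ) inversion and α fitting
- `pirtsim.metrics` — similarity metrics, signed surface distances
- `pirtsim.synthetic` — phantoms, T/B maps, virtual patients
- `pirtsim.pipeline` / `pirtsim.cli` — OER experiments, radial solver, CLI

See `docs/methods.md` for the modelling assumptions, numerical choices
and known limitations.
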