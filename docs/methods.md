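# Methods

This note records the modelling assumptions, numerical choices and
design decisions behind `pirtsim`, and what the synthetic-data tests do
and do not demonstrate about real patient data.

## Governing equations

Tumour cell density c(**x**, t) (cells/mm³) obeys

    ∂c/∂t = ∇·(D(x) ∇c) + ρ c (1 − c/K),

punctuated by instantaneous kill events at each radiotherapy fraction:

    c → c − (1 − S(x)) · c · (1 − c/K),
    S(x) = exp(−α(x) d(x) − β(x) d(x)²),
    α(x) = α/OER(x),  β(x) = β/OER(x)²,

where d(**x**) is the fraction dose from the treatment plan and OER(x)
is 1 outside the hypoxic volume and a constant in [1, 3] inside it.
Dividing α and β by OER and OER² respectively is exactly equivalent to
delivering the reduced dose d/OER at full sensitivity (the standard
dose-modifying-factor convention); the solver exploits this identity and
the test suite asserts it to machine precision.

The density-dependent factor (1 − c/K) in the kill term makes a voxel
at carrying capacity completely unresponsive, representing the necrotic
core, and makes the kill linear in (1 − S) at low density where cells
are actively cycling.  Dead-cell clearance, sublethal-damage repair
(negligible below 2 Gy/fraction), re-oxygenation during the course, and
chemotherapy are deliberately not modelled.

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| D_w | white-matter invasion rate | mm²/yr | 12.84 | mid-range glioblastoma kinetics; patient-specific |
| D_w/D_g | white/grey motility ratio | — | 100 | pioneering migration along myelinated tracts |
| ρ | net proliferation rate | 1/yr | 13.82 | mid-range; patient-specific |
| K | carrying capacity | cells/mm³ | 1.91 × 10⁶ | close packing of 10 µm cells |
| α | LQ radiosensitivity | 1/Gy | 0.055 | patient-specific, fitted |
| α/β | LQ ratio | Gy | 10 | standard tumour-tissue value, held fixed |
| OER | hypoxic dose-modifying factor | — | scenario ∈ {1, 1.5, 2, 2.5, 3} | physiologic range, 1 = oxygenated |
| T/B threshold | hypoxia cut-off on FMISO | — | 1.2 (inclusive) | established FMISO criterion |
| θ_T1Gd, θ_T2 | imaging detection thresholds | fraction of K | 0.80, 0.16 | values used across the proliferation–invasion modelling literature; **not measured for any scanner** — both are configurable everywhere they enter |

The reported invasion rate of a patient is interpreted as the
white-matter rate by default (`d_is_white=True`); whether a published
net rate refers to white matter or a tissue average is convention-
dependent, so the alternative is selectable.

## Numerics

- **Grid**: regular, voxel-centred, 1 mm isotropic by default (matching
  the 1 mm³ phantom convention); anisotropic voxels are supported.
- **Transport**: explicit flux-form central differences with
  harmonic-mean face diffusivities.  The harmonic mean vanishes when
  either neighbour is off-domain, which realizes no-flux boundaries at
  CSF and background without any boundary bookkeeping, and the flux form
  conserves total cell number exactly (verified to < 10⁻⁶ relative per
  1000 steps, the float64 accumulation floor).
- **Reaction**: the logistic term is advanced with its *exact* per-step
  solution, arranged as Strang splitting around the diffusion step
  (half-reaction, diffusion, half-reaction).  A plain forward-Euler
  reaction biases exponential-phase growth by ~ρt·ρΔt/2 — several
  percent per Δt-halving at clinical rates — whereas the split scheme
  changes the final cell count by < 0.5% when Δt is halved at default
  resolution.
- **Time step**: Δt = min(0.9 · dx²/(2·3·D_max), 0.1/ρ) in days
  (rates are divided by 365; fraction schedules are daily events).  The
  first bound is the positivity-preserving explicit-diffusion limit with
  a 0.9 safety factor; the second caps the splitting error.  The radial
  solver uses dr²/(3D) because the centre cell has the largest
  face-area-to-volume ratio.
- **Kill events**: at a fraction time the solver integrates growth and
  diffusion up to the event, then applies the multiplicative kill.
  Negative round-off is clamped to zero (a no-op in practice: the split
  scheme is positivity preserving at the stable step).
- **Fraction calendar**: daily fractions on weekdays (day 0 is treated
  as a Monday), configurable to strictly consecutive days.  The boost
  phase follows the primary phase sequentially, as clinically delivered.

## Calibration conventions

The inversion of serial imaging into (D, ρ) uses two observables: the
radial velocity v of the T1Gd front between two scans, and the
infiltration length λ from the T2–T1Gd equivalent-radius gap.  The
identities v = 2√(Dρ) (Fisher velocity) and D/ρ = λ² then give
D = vλ/2 and ρ = v/(2λ).

The gap-to-λ conversion deserves care.  The exponential leading edge
c ∝ e^(−r/λ) suggests gap = λ·ln(θ_T1Gd/θ_T2) ≈ 1.61 λ, but that
asymptote only holds far ahead of the front where c ≪ K.  Between the
80% and 16% levels the minimum-speed Fisher-KPP travelling wave is much
broader: integrating its profile ODE (U'' + 2U' + U(1 − U) = 0, z in
units of λ) gives a width of ≈ 6.11 λ.  Inverting simulated images with
the exponential rule therefore overestimates D/ρ about 14-fold.
`pirtsim` uses the travelling-wave width as the default conversion and
exposes the exponential convention (and any numeric width factor) as
options, since published estimates differ in exactly this constant.
With the default convention, a virtual patient's (D, ρ) are recovered
within a few percent; the residual comes from voxelization and from the
finite-time approach to the asymptotic wave.

"Bootstrap optimization" of α reduces, for a fixed α/β, to a
one-dimensional monotone problem: post-treatment size is strictly
decreasing in α.  It is solved by bisection on the bracket
[10⁻⁴, 0.5] Gy⁻¹ against the first post-treatment T2 radius, robust to
the step-function character of voxel-counted radii; an observed size
outside the achievable range returns the nearest bracket endpoint,
flagged.

Measured velocity and the Fisher-implied velocity 2√(Dρ) of the fitted
rates are both reported and never silently reconciled — on real data
they can disagree (pre-asymptotic growth, interobserver error of about
±1 mm in radius), and the discrepancy is itself informative.

## Synthetic data

The generator emulates the clinical history its pipeline expects:

- **Phantom**: ellipsoidal head with a ~3 mm grey cortical shell, white
  interior and two off-centre CSF ventricles, blended over ~1 mm into
  fractional tissue probabilities.  It reproduces the *mechanistic*
  roles of anatomy (fast white tracts, grey cortex, CSF obstacles), not
  real gyral geometry.
- **Virtual patient**: a single-voxel seed (0.8 K) grows under known
  (D, ρ) until the virtual T1Gd volume reaches 18.8 cm³; two pre-
  treatment visits 13 days apart are recorded, treatment starts 5 days
  after the second, and the post-treatment MRI follows the last fraction
  by 3 days.  Default target volume, visit interval and schedule mirror
  a representative newly diagnosed glioblastoma presentation.
- **FMISO T/B map**: brain background drawn from a right-skewed
  lognormal whose moments *after truncation below the 1.2 hypoxia
  threshold* match the observed whole-brain statistics 0.813 ± 0.223.
  The truncation is deliberate: an untruncated moment-matched lognormal
  puts ~6% of voxels above threshold, which would swamp the focal
  hypoxic volume with background "hypoxia" — in real images this role is
  played by the spatial coherence of true uptake versus noise.  A
  contiguous focus at T/B = 1.5 covering 13% of the T1Gd volume is grown
  around a point on the tumour surface, so the hypoxic volume straddles
  the dense core and the invasive edge.
- Every generator is a pure function of (config, seed).

What passing tests show: the pipeline's estimators invert its own
forward model correctly at clinical problem sizes, and the scenario
machinery orders hypoxic protection and radiosensitivity effects
correctly.  What they cannot show: performance on real images, where
segmentation error, registration error, MRI/PET physics, non-binary
intravoxel hypoxia and chemotherapy all intervene.

## Problem sizes

Defaults are chosen so the full suite and the end-to-end script run
comfortably on a single CPU: virtual patients use a 96³ phantom at 1 mm;
front-speed checks use a 0.25 mm 1D bar (the 1.6%-accurate resolved
regime); the radial-vs-Cartesian cross-check runs at 0.5 mm with
λ ≈ 2 mm, since an under-resolved front (λ ≈ dx) picks up lattice
anisotropy in 3D that a radial solver cannot share; surface-distance
oracle comparisons use ≤ 32³ grids where the O(n²) brute force is exact
and cheap.

## Known limitations

- Hypoxia is binary per voxel and static over the course: no
  re-oxygenation, no intravoxel oxygen-tension gradients, no kinetic
  FMISO modelling (the blood scaling accepts a scalar activity).
- Dose grids are idealized step functions (no penumbra); arbitrary
  grids can be loaded from NIfTI to bypass the builder.
- No registration: all inputs are assumed coaligned on a common grid.
- The imaging detection thresholds (0.80 K, 0.16 K) are literature
  conventions, not measurements; derived quantities can be re-derived
  under user-supplied thresholds.
- Temozolomide and surgical resection are outside the model; analyses
  should stop at the first post-radiation imaging.
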