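# Methods

## Scope and model

`liverrheo` analyzes parallel-plate rheometry of cylindrical soft-tissue
samples (whole-organ punches, e.g. liver) measured under combined small-
amplitude oscillatory shear and superposed uniaxial strain. The measured
quantities are the first-harmonic storage and loss moduli G′ and G″, the
normal force, and the gap; the derived quantities are geometry-corrected
moduli and axial stresses, segmental Young's moduli, compression-stiffening
and strain-softening statistics, the G′-versus-axial-stress line, hysteresis
ratios over repeated amplitude cycles, and normalized stress-relaxation
curves.

At the core is a deliberately minimal constitutive surface with **two
material parameters** per sample:

- `C1` (Pa): baseline low-strain shear storage modulus at zero axial strain;
- `C2` (Pa): axial nonlinearity scale.

With axial engineering strain λ = (h − h₀)/h₀ (compression negative, tension
positive) and shear amplitude γ:

- axial stress (compressive positive): σ(λ) = C₂(e^{−bλ} − 1);
- tangent Young's modulus: E(λ) = −dσ/dλ = C₂·b·e^{−bλ};
- storage modulus: G′(γ, λ) = [C₁ + m·σ(λ)]·s(γ, λ), with the Hill-type
  softening factor s = 1/(1 + (γ/γ_eff)^n) and
  γ_eff = γ_c·(1 + max(σ, 0)/σ_ref);
- loss modulus: G″ = tan δ · G′ with a fixed loss tangent.

This functional form is this package's own reference surface, constructed so
that the qualitative phenomena of interest hold identically: G′ is exactly
affine in the axial stress at fixed (small) γ, compression stiffens and
tension softens both G′ and E, G′ decreases monotonically in γ, and the
softening curve flattens (γ_eff grows) under compression. It is isolated
behind `storage_modulus_model` / `axial_stress_model` so that a different
strain-energy-derived surface can replace it without touching the pipeline.

### Shape constants (fixed, not fitted)

| constant | default | units | meaning |
|---|---|---|---|
| `b` | 8 | – | axial exponential rate; E(0) = b·C₂ |
| `m` | 0.8 | Pa/Pa | slope of G′ against axial stress |
| `gamma_c` | 0.22 | – | softening half-strain at zero compression |
| `n_soft` | 3 | – | softening sharpness |
| `sigma_ref` | 4000 | Pa | stress scale for softening flattening |
| `tan_delta` | 0.2 | – | loss tangent G″/G′ |

`b = 8` puts the E(−25%)/E(0) ratio at e² ≈ 7.4, a realistic strong
compression stiffening over the protocol's strain range while keeping
E ≤ 10·G′ on all presets. `n_soft = 3` was chosen so that the standard 1–2%
reference amplitudes sit on a genuine low-strain plateau (softening < 0.1%
there); this makes the 2% readout an unbiased estimate of the plateau
modulus and the compression curve at 2% affine in axial stress to ≲0.1%,
which is what the structural-linearity check requires. A smaller exponent
(e.g. 1.3) leaks several percent of softening into the 2% readout and biases
the recovered slope/intercept accordingly. `tan_delta = 0.2` reflects a
tissue whose loss modulus is roughly a fifth of its storage modulus.

Fixing the shape constants preserves the two-parameter structure: `fit()`
estimates only (C₁, C₂).

## Synthetic rheometer

The generator is a lumped-sample instrument emulator, not a spatially
resolved tissue model. For each measurement plateau it evaluates the
phantom's surface at the active (γ₀, λ) and writes sinusoidal waveforms (64
samples/period, 2 periods per plateau):

    stress(t) = f · γ₀ · (G′_meas · sin ωt′ + G″_meas · cos ωt′)

where the *measured* moduli are the actual surface values divided by
(1+λ)² — the exact inverse of the geometric correction — so that
extraction followed by correction closes on the generating surface exactly
at zero noise. `f` is a unit-mean log-normal factor with coefficient of
variation `noise_cv` (default 0.05), drawn **once per plateau**: repeated
extracted G′ then has sample CV equal to `noise_cv`, and the G″/G′ ratio is
noise-invariant, as for a gain-type transducer error. The normal-force
channel adds independent Gaussian noise (SD 0.01 N).

The normal force carries the 10 g preload as a constant true-stress offset
(312.2 Pa on a 20 mm punch) plus the surface's equilibrium axial stress
scaled by a two-mode Prony transient

    M(t) = 1 + Σᵢ (gᵢ/g_inf)·e^{−t/τᵢ},   g = (0.25, 0.15), τ = (8 s, 25 s),

applied from the moment of each axial step. With these time constants the
transient residual at the 120 s readout is ~0.2%, consistent with treating
the last time-sweep plateau as the equilibrium value; the equilibrium
fraction g_inf = 0.6 gives a visible relaxation plateau well before the
1200 s relaxation protocol ends. Stress-relaxation kinetics are independent
of punch diameter by construction: the emulated tissue relaxes by intrinsic
viscoelasticity, with no size-dependent (poroelastic) fluid-flux mode.

Condition presets (`C1`, `C2` in Pa): normal (1000, 250), early fibrosis
(2000, 500), established fibrosis (4000, 1200), amylase (1000, 80), VLO4
(1000, 90), permeabilized (850, 230), decellularized (100, 2, softening
disabled). These encode ordinal phenotypes — fibrosis raises both
parameters; glycosaminoglycan digestion and integrin blockade suppress
compression stiffening at normal baseline stiffness; decellularization
removes ~90% of the baseline modulus along with compression stiffening and
shear softening. The decellularized `C2 = 2` keeps its stiffening ratio
below 1.2 ("almost complete loss"). Reversibility cycles apply a one-time
5% stiffening factor after the first cycle and none thereafter.

What the generator does **not** emulate: instrument inertia and compliance,
higher harmonics at large amplitude, sample-platen slip or imperfect
contact, drift, sample heterogeneity, poroelastic size effects, and
temperature effects. Passing tests therefore demonstrate that the analysis
chain correctly inverts a tissue of this idealized class at realistic noise
levels — not that real organ data are free of those artifacts.

## Analysis chain

- **Harmonic extraction** (`oscillation.fit_harmonics`): the strain channel
  is least-squares projected onto {sin ωt, cos ωt} first to fix amplitude
  and phase, then the stress is decomposed relative to the strain phase;
  this makes the result exactly invariant to global time shifts and robust
  to cropping. At least one full period is required. Segmentation uses trace
  metadata when present; the metadata-free fallback splits on jumps in the
  sampling grid and rejects non-plateau amplitudes (>2% first-half/second-
  half amplitude disagreement) with the offending timestamp named.
- **Geometric corrections**: G′, G″ and axial stress are all multiplied by
  (1+λ)², applied exactly in this quadratic form in both compression and
  tension; the exponent is an explicit argument for sensitivity analysis.
  Conversions use g₀ = 9.80665 m s⁻² and 1 mm Hg = 133.322 Pa.
- **Per-plateau normal force** is the mean over the final 10% of the
  plateau's samples (the most relaxed value); "G′ at 120 s" is the last
  record of a time sweep.
- **Segmental E**: Δσ between neighboring axial levels divided by Δ|λ|,
  reported positive in compression; constant stress offsets (the preload)
  cancel exactly. The sign convention is auto-detected (signed λ when any
  strain or stress is negative, compressive-magnitude otherwise) and can be
  forced.
- **G′–stress line**: OLS of the corrected 2%-amplitude, 120 s G′ on the
  corrected axial stress across levels, with the preload stress subtracted
  from the regressor so the intercept estimates the zero-deformation
  modulus. Axial stress elsewhere is reported preload-inclusive.
- **Softening statistic**: γ_half, the amplitude at which G′ falls to half
  its first-grid-point plateau, by linear interpolation on the measured
  grid; a flat curve reports γ_half as absent with end ratio 1. This is the
  package's operationalization of curve steepness and is monotone-equivalent
  to it.
- **Relaxation comparison**: both curves are converted to deformation
  stress (corrected, preload-subtracted for compression mode), resampled
  onto a common grid restricted to t ≥ 5 s (early times are step-loading
  artifacts), normalized by the first common grid value, and compared
  pointwise. Note the preload offset itself scales with 1/area and can never
  be diameter-invariant; the deformation stress is.

## Fitting and uncertainty

`CompressionShearModel.fit()` minimizes joint relative residuals (divisor
|observed| + 1 Pa, so kPa-scale stresses do not dominate Pa-scale moduli)
over (C₁, C₂) with `scipy.optimize.least_squares` (trf, bounds C₁ ∈
(0, 10⁶], C₂ ∈ [0, 10⁶] Pa), from three data-driven starts (C₁ ← low-strain
G′ near λ=0; C₂ ← inverted deepest-compression stress; ×0.5 and ×2 scalings)
because joint convexity is not guaranteed. Standard errors come from the
Gauss–Newton covariance s²(JᵀJ)⁻¹. A single axial level raises an
identifiability error for C₂ rather than returning a spurious fit.

## Problem sizes and determinism

Default validation runs use the full compression series (5 axial levels ×
(7 time-sweep + 11 amplitude-sweep plateaus), 128 samples per plateau) and
5-replicate recovery experiments; these sizes give sub-second pipeline runs
while leaving parameter-recovery error well below the noise floor of
interest. All randomness flows from `numpy.random.default_rng` seeded per
phantom, with per-protocol streams spawned via `SeedSequence`, so identical
(phantom, protocol, seed) yield bit-identical traces and files.

## Known limitations

- The constitutive surface is phenomenological; its parameters should not
  be over-interpreted microstructurally.
- The quadratic (1+λ)² stress correction is applied as a fixed convention
  even though a pure volume-conservation area argument would give a single
  power; the exponent argument exists precisely to probe this choice.
- γ_half is undefined for curves that never soften below half their
  plateau within the measured range (reported as absent, not extrapolated).
- The fit assumes the shape constants are known; misspecified shape
  constants bias (C₁, C₂) rather than being detectable from the residuals
  at these problem sizes.
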