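# Methods

## Quadratic temperature models

Every temperature-dependent quantity handled by the package — dynamic
viscosity μ (mPa·s), relaxation times T1/T2 (ms), and the in-cadaver
perfusate temperature ϑ_P1 (°C) — is described by the same empirical
quadratic form

    q(ϑ) = q(ϑ_ref) + A·Δϑ + B·Δϑ²

in a signed temperature offset Δϑ from a fixed reference temperature
(20 °C for viscosity, 23 °C for relaxation times, 31.6 °C — the warmest
observed cadaver — for the in-cadaver temperature model). The quadratic is
an empirical fit over the forensically relevant 0–25 °C band, not a
physical law; no Arrhenius/VFT viscosity model is offered, and evaluation
outside 0–40 °C only warns (`ExtrapolationWarning`) rather than fails.

**Sign convention.** The published coefficient tables define
Δϑ = ϑ_ref − ϑ, yet the observed correlations (viscosity falls with
temperature, relaxation times rise) correspond to the mirror convention
Δϑ = ϑ − ϑ_ref with the same printed coefficients. Rather than silently
deciding, `delta_convention` is a mandatory field of every model:
`as_printed` reproduces the tables' printed claims (e.g. the 27–33 mPa·s
viscosity window of the preferred perfusates over 8–20 °C, recomputed by
`scripts/acceptance.py`), while `physical` produces the physically ordered
behaviour and is used by the synthetic-data generators and the simulation
pipeline. The two conventions agree at the reference temperature and are
exact mirror images about it; neither is asserted as "correct".

**Fitting.** `fit_quadratic` is ordinary least squares in the Δϑ basis,
with the intercept either free (needs ≥ 3 distinct temperatures and
df = n − 3 ≥ 1) or fixed to a supplied/measured reference value (df = n − 2;
this is how viscosity models are refit from the three-temperature 8/10/20 °C
protocol). Residual standard error is RSE = √(RSS/df) with df counting
fitted parameters only; coefficient standard errors come from the usual
(XᵀX)⁻¹·RSE² expression. Duplicate temperatures make the design
rank-deficient and raise a fit error rather than returning a pseudo-inverse
solution.

The packaged registry (`data/registry.json`) carries the printed
coefficients of the nine experimentally characterised liquids verbatim,
plus the in-cadaver temperature model
ϑ_P1 = 28.4 + 0.835·Δϑ_EE + 0.014·Δϑ_EE² (RSE 0.8778 °C, coefficient SEs
0.06 and 0.003). Whether the published intercepts were fixed or fitted is
not recoverable from the tables; the registry stores them verbatim and the
fitter supports both modes.

## Relaxometry

T1 is estimated from the three-parameter inversion-recovery model
S(TI) = S0(1 − 2A·e^(−TI/T1)), where A ∈ [0.5, 1.5] absorbs incomplete
inversion; T2 from the mono-exponential decay S(TE) = S0·e^(−TE/T2). Both
use bounded nonlinear least squares (scipy trust-region reflective, bounds
T1/T2 ∈ (0, 20000] ms) with up to three deterministically jittered restarts;
failures raise a `FitError` carrying the best candidate.

Numerical choices:

* **T1 initialisation**: T1 ≈ TI_zero-crossing/ln 2 (interpolated when the
  signed data change sign, else the minimum-|S| TI), S0 = max|S|, A = 1.
* **Polarity**: magnitude-reconstructed IR data lose the sign of early-TI
  points. `restore_from_magnitude` (the default) tries every candidate
  crossing position c = 0..n, negates the first c points, and keeps the
  assignment with minimum RSS — an exhaustive search over at most n + 1
  bounded fits. Fits whose best assignment implies no sign change inside
  the TI span are flagged, not rejected.
* **T2 initialisation**: log-linear regression on the retained echoes,
  falling back to a direct start when any retained signal is non-positive.
* **First echo**: the first echo of a multi-echo spin-echo train is
  systematically contaminated (stimulated-echo pathways) and is discarded
  by default before fitting; with a 32-echo train, 31 echoes enter the fit.

The ROI procedure is *average-then-fit*: the voxels of each slice are
averaged first (unweighted; voxel counts are kept as provenance only) and
each slice's averaged series is fitted independently. The summary over
slice estimates reports the mean, the sample (n − 1) standard deviation and
RSD = 100·SD/mean; failing slices are excluded and listed. No
fit-then-average mode and no multi-exponential models are provided.

## Spoiled-GRE simulation

The simulator represents one voxel as `n_spins` isochromats (default 100)
evolving under the hard-pulse approximation for `n_excitations` TRs
(default 100). Per TR: instantaneous rotation by the flip angle about a
transverse axis at RF phase φ_k; relaxation to TE; the sample is the
magnitude of the isochromat-mean complex transverse magnetization
(receiver demodulated at φ_k); relaxation to TR; then the spoiler gradient
adds the fixed intravoxel phase spread θ_j = 2πj/n_spins. The RF phase
follows the standard quadratic schedule φ_k = Δφ·k(k+1)/2 with Δφ = 117°
(a linear schedule is available behind `phase_schedule="linear"`). There
are no random phases: the simulation is deterministic and bit-reproducible.
The returned signal is the final-excitation sample; the full per-excitation
trace is available for convergence inspection. Slice profile, B0/B1
inhomogeneity, diffusion, flow and T2* are not modelled.

**Validation against the Ernst closed form.** Under ideal spoiling the
steady-state signal is S = M0·sin α·(1 − E1)/(1 − E1·cos α)·e^(−TE/T2),
E1 = e^(−TR/T1). Two genuine physical limits of the 117° RF-spoiling
approximation surfaced during validation and are reflected in the test
suite:

* Agreement with the Ernst form within 5 % holds across
  T1 ∈ [100, 1100] ms and T2 ∈ [100, 600] ms for flip angles up to ≈ 20°,
  and at the package's reference case (paraffin oil at 23 °C, flip 30°,
  ≈ 3 %). At larger flip angles with T2 long relative to TR the residual
  transverse coherence that RF spoiling cannot scramble grows to tens of
  percent (up to ≈ 59 % at T1 = 1100 ms, T2 = 600 ms, flip 90°). This was
  cross-checked against an independent rotation-matrix Bloch implementation
  (agreement to 6 decimals), i.e. it is the physics of imperfect spoiling,
  not a solver artefact.
* After 100 excitations the final sample is converged to < 1 % (vs doubling
  the excitation count) for T1 ≤ ≈ 700 ms; at T1 = 1000 ms, 100·TR = 2·T1
  still leaves ≈ 2 % residual transient near the Ernst angle. The approach
  is smooth and monotone.

**Contrast analysis.** Contrast is the signed per-flip signal difference
C = S_perfusate − S_tissue on a shared integer flip grid. The optimal flip
set contains every grid angle whose contrast, rounded to four significant
figures, equals the rounded maximum; one or two angles are expected, and
more than two ties are truncated to the two smallest with a warning. Across
temperatures the union of optimal sets defines a flip range (with a gap
warning if the union is not contiguous), and per temperature
d_r = |C_opt − C_min|/|x̄_opt,min|·100 quantifies the contrast penalty of
using any angle in that range, where C_min is the minimum contrast over the
range. Because the contrast curve is very flat on top, optimal-angle
*positions* from the simulator and from the Ernst oracle can differ by a
few degrees while the achieved contrast differs by ≈ 1 %; validation
therefore compares achieved contrast, not argmax position.

**Tissues.** Perfusate relaxation values at each simulation temperature
come from the registry models (physical convention). Tissue relaxation
values are user-supplied single-temperature (T1, T2, M0) triplets; the
packaged `data/tissues_synthetic.json` contains clearly-labelled synthetic
placeholders with plausible magnitudes (myocardium-like 900/45 ms,
fat-like 380/110 ms, equal proton density) so the pipeline runs end to end.
Conclusions about real tissue contrast require measured values.

## Synthetic data

The generators emit data with the statistical structure the analysis
assumes, under the study's own conditions:

* **Cadaver records** (default n = 21): ϑ_EE uniform over the observed
  9–31.6 °C span, ϑ_P1 from the in-cadaver model (physical convention)
  plus Gaussian noise with σ = 0.8778 °C (the model's residual standard
  error), ϑ_P0 uniform over the 20–24 °C storage band, dwell time uniform
  over 1–23 min. Only ranges are reported for the covariates, so uniform
  distributions are the maximum-entropy choice.
* **IR series** at the scanner protocol TI = {50, 100, 200, 350, 600,
  1000, 4000} ms with S0 = 1000, A = 1; **MSE trains** at echo spacing
  10.6 or 20 ms with 32 echoes and a first echo inflated by 10 % by
  default, emulating the artifact that motivates the discard rule. Noise
  is Gaussian on the signed signal with σ = 1 % of S0 by default (matching
  the reported RSD < 3.2 % dispersion of the study's slice estimates), or
  Rician on the magnitude.
* **Viscosity triplets** at 8/10/20 °C with σ defaulting to the model's
  RSE; density is uniform over 0.8–1.15 g/cm³ (the span of the studied
  liquids) with kinematic viscosity back-filled as μ/ρ.

All generators are pure functions of (seed, parameters). What they do
*not* emulate: image-domain noise correlation, coil sensitivity, B1 and
inversion-efficiency spatial variation, partial volume, or any systematic
drift between temperature steps. Passing recovery tests on these data
therefore demonstrate estimator correctness and statistical consistency
under the assumed noise model, not robustness to scanner systematics.

## Problem sizes and defaults

Monte-Carlo checks use 200–500 seeded replicates (cohort refits at n = 21;
relaxometry at the acquisition protocol sizes), chosen to make standard
errors on recovered coefficients a small fraction of the assertion bands.
The acceptance script evaluates the viscosity window on a 1201-point grid
over 8–20 °C. CSV/JSON outputs are written at 6 significant digits, which
makes byte-identical reproduction testable and bounds model-coefficient
round-trips through the interchange format at ~10⁻⁴ relative.

## Known limitations

* The quadratic models are interpolations over sparse temperature grids
  (3–4 points); the registry's RSE values cannot be re-derived without the
  underlying raw measurements.
* Magnitude-polarity restoration assumes a single zero crossing
  (mono-exponential recovery); multi-compartment voxels violate this.
* The simulator's ideal-spoiling agreement degrades for long-T2 liquids at
  large flip angles (see above) — this is a property of RF-spoiled
  sequences themselves and means Ernst-formula shortcuts are unreliable
  exactly where oil-like perfusates live.
* Packaged tissue values are synthetic placeholders; simulated contrast
  against them demonstrates the machinery, not a clinical prediction.
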