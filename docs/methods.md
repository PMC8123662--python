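# Methods

This note documents the models behind `gwire`, the parameter choices, the
synthetic-data generators, and the numerical decisions, in enough detail
to judge what a passing test suite does and does not demonstrate.

## Correlation model

Dynamic light scattering measures the normalised intensity
autocorrelation g₂(t). In dilute G-quadruplex solutions two diffusive
modes are typical: a fast mode from the quadruplexes and their stacked
multimers, and a slow mode from large, loose polyelectrolyte clusters
(micrometre scale, not directly related to quadruplex formation). Each
mode is modelled as a stretched exponential and mapped to g₂ by a
partial-heterodyne Siegert-type relation:

    g₂(t) − 1 = [ j_d ( a_f e^{−(t/τ_f)^{s_f}} + (1−a_f) e^{−(t/τ_s)^{s_s}} ) ]² + y₀

- `j_d ∈ (0, 1]`: fraction of the detected intensity that is dynamically
  (inelastically) scattered; j_d² is the t = 0 intercept of g₂ − 1.
- `a_f ∈ [0, 1]`: fast-mode amplitude; a_f = 1 expresses a single-mode
  decay (no separate model type).
- `τ_f < τ_s`: relaxation times (s); for diffusive modes τ = 1/(Dq²).
- `s_f, s_s ∈ (0, 1]`: stretch exponents; 1 for a monodisperse
  single-rate decay, smaller for a distribution of relaxation times.
- `y₀`: small baseline correction.

The mapping from the field correlation to g₂ is isolated in
`dls_model.intensity_from_field` so that an alternative heterodyne
convention (e.g. |1 + j_d(g₁ − 1)|²) can be substituted in one place if a
different correlator convention is needed.

The scattering vector is q = (4πn/λ)sin(θ/2). Angles are degrees at
every public interface and radians internally; all stored quantities are
SI, with the conventional 10⁻¹⁰ m²/s display unit for D applied only at
output boundaries.

## Fitting

`fit_curve` performs unweighted bounded least squares (lmfit /
`scipy.optimize.least_squares`) on g₂ directly. Choices that matter:

- **Initialisation** (`default_init`): j_d from the square root of the
  early-lag plateau of g₂ − 1; τ_f from the 1/e crossing of the implied
  field correlation; τ_s = 100·τ_f; a_f = 0.8; s = 0.95; y₀ = 0.
- **Multi-start**: 5 deterministic, seed-derived perturbations of the
  initialisation (log-normal factors on the times, jitter on amplitudes
  and stretch). Best residual wins; near-ties go to the smaller τ_f.
- **Mode ordering** is enforced structurally: the optimiser works with
  τ_s = τ_f · ratio, ratio ≥ 1.
- **Stretch bounds** [0.3, 1.0] during fitting (configurable): the lower
  bound keeps the optimiser away from degenerate ultra-stretched
  solutions that can mimic any decay.
- **Mode-count selection** (`n_modes="auto"`): a two-mode fit is tried
  first; if it collapses (a_f > 0.99, a_f < 0.1, or τ_s/τ_f < 5) the
  curve is refit with one mode, which is kept unless its residual RMS is
  more than 10% worse. Two modes are typical but not universal in real
  measurements, and a two-mode fit of one-mode data is ill-posed without
  this guard.
- **Tolerances**: ftol = xtol = gtol = 10⁻¹⁴, so noiseless round-trips
  recover parameters to ~10⁻⁶ relative or better.

The diffusion coefficient comes from ordinary least squares of 1/τ_f on
q² (`diffusion_from_rates`). The intercept is free by default — robust
to a constant rate offset; a pure diffusive process has intercept 0 —
and can be constrained to the origin, which is also the automatic
fallback when only two angles are available. The reported stretch
exponent is the arithmetic mean (± standard error) of s_f over angles;
the slow-mode exponent is not averaged in.

## Rod hydrodynamics

For a rigid rod of length L, diameter d, aspect ratio p = L/d in
2 ≤ p ≤ 30:

    D = k_B T / (3πηL) · (ln p + ν(p)),   ν = 0.312 + 0.565/p + 0.100/p².

Defaults: d = 2.6 nm (a G-quadruplex including its hydration sphere),
T = 296 K, η = 0.932 mPa·s (aqueous solvent at that temperature).
Temperature-dependent viscosity is deliberately not modelled — η is a
user input, because analyses are run at one (T, η) pair.

With these defaults the formula is considered reliable for
5 nm ≤ L ≤ 80 nm, corresponding to 1.197 ≥ D ≥ 0.218 × 10⁻¹⁰ m²/s
(computed from the parameters, never hard-coded; conventionally quoted
as 1.2 and 0.22). Two flags are reported separately: the aspect-ratio
window (2 ≤ p ≤ 30) and the length window, because they disagree
slightly at the short end (p = 1.92 at L = 5 nm, where the formula is
customarily still applied).

**Inversion.** D(L) is strictly decreasing, so `length_from_diffusion`
uses Brent root finding on the [5, 80] nm bracket (relative tolerance
10⁻⁶). Outside the corresponding D-range the bracket widens to
[1.1·d, 1 µm] only when extrapolation is explicitly allowed, and the
result is flagged: beyond p = 30 the number is best read as a lower
bound ("longer than ~80 nm"), not a length measurement. Note that
inverting exactly at the conventional 1.2 × 10⁻¹⁰ m²/s bound requires
the widened bracket, since the printed bound is rounded up from the
exact window edge.

**Multimer counts.** n_planes = round(L / 0.34 nm) and
n_units = round(n_planes / 4), round-half-up, floored at 1. Four planes
per unit reflects a quadruplex with four G-quartets; both the axial rise
and planes-per-unit are parameters, because the effective rise per
stacked unit depends on the fold and interface geometry of the
particular sequence and is not settled.

## Synthetic DLS data

The generators define the conditions the fitting stages are tested
under:

- **Monodisperse**: per angle, τ_f = 1/(D q²) exactly; optional slow
  cluster mode specified directly by D_slow (clusters are not modelled
  geometrically — their sizes are only known to be "micrometre range",
  so the generator exposes the rate instead). Curves are evaluated on a
  200-point log-spaced lag grid from 10⁻³·τ_f to 10³ times the slowest
  relaxation (correlator-like; configurable).
- **Rod ensembles**: n component lengths drawn once per dataset (the
  same physical sample viewed at all angles) from delta, lognormal or
  uniform distributions; per-component D from the rod formula; field
  correlation Σ wᵢ e^{−D(Lᵢ)q²t} with intensity weights wᵢ ∝ Lᵢ²
  (scattering cross-section grows as the squared scattering volume; for
  rods of equal diameter, the squared length). A polydisperse ensemble
  is strictly multi-exponential, so a single stretched-exponential fit
  returns s_f < 1, and wider distributions give smaller s_f. Note the
  L² weighting concentrates the signal on the longest rods, so the drop
  in s_f with distribution width is real but modest.
- **Noise**: multiplicative Gaussian on g₂ − 1 plus an additive Gaussian
  floor, both 0.5% in the "realistic" default spec and 0 unless
  requested; one named generator seeded explicitly, so identical seeds
  give bit-identical datasets. Real correlator noise is
  lag-time-correlated and photon-statistics driven; this white-noise
  model is simpler, which means recovery tests here bound estimator
  quality under idealised noise only.
- **Denaturation series**: one monodisperse dataset per (time, D) point
  with per-point seeds derived from the series seed — a stand-in for
  re-assembly kinetics after thermal denaturation, with no kinetic model
  implied.

Default simulated study conditions used throughout the tests and the
reproduction script: six angles 30–130° in 20° steps, λ = 633 nm,
n = 1.33, 1% multiplicative noise for "noisy" scenarios, cluster mode at
D_slow = 0.05 × 10⁻¹⁰ m²/s with a_f = 0.8.

## AFM morphometry

Segmentation takes 8-connected components of pixels with height ≥ 1 nm
(the threshold that separates adsorbed quadruplex material from the mica
background in air imaging). Per object: maximum and mean height, pixel
area, and end-to-end extents along the two principal axes of the pixel
cloud (one pixel footprint added to the centre-to-centre span). Height
is summarised as the per-particle maximum — robust to edge tapering —
with the mean also recorded.

- **Wire classification**: elongation (length/width) ≥ 2 by default. The
  threshold is a design choice ("elongated" is not quantified in
  standard practice) and is configurable.
- **Length convention**: principal-axis end-to-end extent, not skeleton
  arc length. For straight or gently curved wires the two agree; for
  strongly bent wires the extent underestimates the contour length, and
  ridge-tracing methods (e.g. Steger-style line detection) would be
  needed. That algorithm is deliberately out of scope.
- **Tip correction**: measured wire lengths minus a constant 15 nm
  (clamped at zero), reflecting the lateral broadening by a finite tip.
  A constant offset is the simplest usable model; full tip-shape
  deconvolution is out of scope.
- **Salt artefacts**: residual buffer salts can deposit circular
  structures of varying height. Rinsing removes most, but the
  segmentation cannot distinguish a salt grain from an island — a
  documented caveat, not a filter.

The synthetic film generator places non-overlapping disks and capsule-
shaped rods (heights Gaussian around 2.3 nm, matching air-dried
quadruplex layers) on a flat background, then emulates tip broadening by
grey-scale dilation with a disk structuring element of radius
tip_broadening/2 — which lengthens rods by ≈ tip_broadening and
preserves maximum heights, so height statistics survive broadening
exactly while lengths need the correction. Objects are placed with a
one-tip-diameter margin so broadening cannot merge them; real films do
show merged and overlapping structures, which this generator does not
exercise.

## Numerical and interface decisions

- Validation errors (bad inputs, out-of-domain arguments, malformed
  files) and computation failures (non-convergence, no bracketed root)
  are distinct exception types; the CLI maps them to exit codes 2 and 3.
- Failed per-angle fits and failed time points are flagged in results,
  never silently dropped.
- `fit_curve` is deterministic given (curve, init, seed); pipeline
  reports are byte-identical for identical inputs and configuration
  (no timestamps in the JSON).
- Problem sizes in the tests and the reproduction script — 200-point
  curves, six angles, ≤ 64-component ensembles, ≤ 1024² px films — were
  chosen as the smallest sizes representative of a real measurement
  session.

## Known limitations

- No inverse-Laplace (CONTIN-style) analysis, cumulant analysis, or
  global multi-angle fitting; each curve is fit independently.
- Rod hydrodynamics only: no flexibility (wormlike-chain) or
  electrostatic corrections to D. For 100 mM added monovalent salt,
  screening makes the polyelectrolyte correction negligible; at low
  ionic strength the inferred lengths would be biased.
- The printed form of two-mode correlation models varies between labs;
  the Siegert-consistent convention adopted here (j_d² as the intercept)
  is documented above and swappable in one function.
- Synthetic data validate the estimators under the stated generating
  assumptions; they cannot certify performance on curves with afterpulsing,
  number fluctuations, dust events, or baseline drift.
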