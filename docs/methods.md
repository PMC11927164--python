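# Methods

This note documents the models implemented in `stochrange`, the default
parameters and why they were chosen, what the synthetic data generators do
and do not emulate, and the numerical decisions that matter for
reproducing results.

## Resource environments

Resources at time *t* are a random variable *R* with mean μ(t) and
variance σ²(t).  Both trajectories are chosen from five temporal patterns:

| kind     | definition | parameters (defaults for the mean / variance grids) |
|----------|------------|------------------------------------------------------|
| constant | μ(t) = level | 2.75 / 4.0 |
| linear   | intercept + slope·t | 0.5→5 / 0.25→50 across the window |
| cyclical | baseline + amplitude·sin(2πt/period) | 2.75 ± 2.25, period = half window / 12.5 ± 12 |
| drifting | positivity-clamped Gaussian random walk on a fixed 101-point lattice, linearly interpolated | step SD 0.2 / 1.0 |
| erratic  | independent log-normal draw per lattice point, piecewise constant | median 2, sdlog 0.5 / median 4, sdlog 1.2 |

The first three are deterministic and consume no generator state; the last
two are frozen, bit-reproducible functions of their seed.  The positivity
clamp floor is 1e-6 resource units, the minimum needed for valid Gamma
moments.  Resource amounts are drawn from Gamma(μ, σ²) via the moment map
shape = μ²/σ², scale = σ²/μ (so the coefficient of variation alone fixes
the shape), or Beta(μ, σ²) via α = μν, β = (1−μ)ν, ν = μ(1−μ)/σ² − 1,
which requires σ² < μ(1−μ).

Spatial heterogeneity is deliberately absent from the simulation stage
(environments are homogeneous at any given *t*); space-time structure
lives only in the case-study module.

## Movement and foraging

Three planar Gaussian processes with independent, identically
parameterized axes:

- **IOU** (exploratory, endlessly diffusive): OU velocity with timescale
  τ_v and stationary variance σ_v²; position is its integral.  With the
  velocity initialized from its stationary law, the per-axis position
  variance is exactly 2σ_v²τ_v[t − τ_v(1 − e^(−t/τ_v))].
- **OU / OUF** (range-resident): stationary position with crossing
  timescale τ_p and per-axis variance ς²; OUF adds correlated velocity
  (τ_p > τ_v) with autocovariance
  ς²(τ_p e^(−τ/τ_p) − τ_v e^(−τ/τ_v))/(τ_p − τ_v).

Sampling uses the exact joint Gaussian state transition over each step
(for OUF via the eigendecomposition of the drift matrix and
Q = P∞ − Φ P∞ Φᵀ), so halving the step changes nothing but the sampling
density — a property the test suite checks directly against the closed
forms.

Foraging walks a track across an origin-anchored grid of half-open square
cells (floor indexing; boundaries belong to the +x/+y side).  Every entry
into a cell different from the current one yields one independent Gamma
draw — revisits are rewarded afresh because resources do not deplete; a
strict first-visit-only mode exists for sensitivity analysis.  The track
is truncated at the first fix where the cumulative collection reaches the
satiety target *C*; tracks that never reach it are censored at the search
ceiling and retained with a flag (downstream fits use the truncated
positions either way).

Default study conditions (abstract distance/time units): τ_v = 1,
σ_v² = 1, sampling step dt = 0.2, cell size 0.3 (≈ one step length, so a
median track changes cells every ~1.3 fixes), satiety C = 10, ceiling 4
time units.  The reasoning: by renewal/Wald arithmetic the expected number
of collections to reach satiety is ≈ (C + (σ² + μ²)/(2μ))/μ — the second
term is the expected overshoot of skewed draws — so resource variance
only moves search times appreciably once σ² is comparable to μ·C.  The
variance trajectories therefore reach ~50 (well above the squared
means), and the ceiling of 4 time units binds at the poorest means even
under low variance (search at μ ≈ 0.9 needs ~12 collections at ~0.26
time units per cell change, already at the cap), encoding the premise
that exploration time in a finite lifetime caps range size.  Under these
conditions mean range size falls with E(R), rises with Var(R) with a
sublinear saturation at high Var(R), and the variance effect on the mean
range is strongest at high E(R), where searches are short and never hit
the cap.

Sessions start every track at ⟨0,0⟩ with stationary initial velocity and
treat tracks as independent (the return-to-origin interlude is not
simulated; independence is the contract).  RNG policy: one root
generator, one spawned child stream per track, so any single track is
reproducible in isolation.

## Likelihood, fitting, home ranges

The joint likelihood of a set of segments under a shared movement model is
the exact zero-mean Gaussian density of all fixes, evaluated by sequential
conditioning on the (position[, velocity]) state — linear in the number of
fixes and equal to the dense-covariance density to ~1e-15 relative (tested
against an independently coded dense oracle).  Positions carry no
measurement error, so the update step conditions exactly.  IOU likelihoods
are conditional on each segment's first fix with stationary velocity
prior.  For stationary families the pooled empirical mean location is
subtracted first (profile estimate of the range center).

Fitting maximizes over log-transformed parameters (for OUF over
(log ς², log τ₁, log τ₂), exploiting the symmetry of the autocovariance in
the two timescales; labels are assigned by size afterwards) with
Nelder-Mead polishing into BFGS from a moment-based initialization plus
two restarts with timescales ×10 and /10.  Parameter covariance is the
inverse central-difference Hessian on the log scale; the convergence flag
is honest (optimizer success *and* a positive-definite Hessian).
Innovation variances are floored at 1e-10 of the pooled data variance.

A fitted ς² converts to the area of the central q-quantile of the
circular Gaussian utilization distribution, H_q = −2 ln(1−q)πς²
(≈ 18.8227 ς² at q = 0.95).  Note that the IOU-generated, satiety-truncated
foraging segments are *nonstationary* yet are fitted with the stationary
OUF family; the resulting ς̂² is interpreted as the effective range
parameter of the session, which is precisely the estimator whose response
to μ and σ² the experiment studies.  Effective sample size is
duration/τ̂_p (observed range crossings); a crossing time counts as
resolvable only when τ̂_p is finite with a finite Wald upper bound;
diffusion is ς̂²/τ̂_p (range-resident) or σ̂_v²τ̂_v (IOU).

Wald-interval calibration was checked by self-simulation: across 200
sessions of 20 OUF segments, 95% intervals covered the true ς², τ_p, τ_v
in 96%, 96% and 92.5% of replicates.

## Location-scale regression

Both response moments are modeled as sums of penalized spline smooths:
Gamma family (log mean, log scale, Var = s·μ_H² — the convention that
makes the "variance surface" below unambiguous) and Beta family (logit
mean, log precision, Var = μ(1−μ)/(1+φ)).  Bases are B-splines of degree
3 (degree 2 at k = 3) with second-difference penalties and a sum-to-zero
constraint absorbed by a QR null-space transform; two-covariate
interactions are tensor products of the constrained marginal bases, which
excludes both main effects (a ti()-style term).  Coefficients maximize
the penalized likelihood by full Newton iterations with analytic
gradients and Hessians and step halving (the penalized objective is
non-increasing by construction).  Credible intervals come from
multivariate-Gaussian draws centered at the penalized MLE with the
inverse penalized Hessian as covariance.

Every penalty component is normalized by the likelihood curvature on its
own coefficient block, making smoothing weights dimensionless.  Each term
carries two components: its curvature penalty and a projector on the
penalty's null space, so a term can be shrunk out of the model entirely.
With `smoothing="auto"` both are selected by coordinate-descent AIC over
a log-spaced grid; with fixed weights one number per term scales both.
For the six-term scenario-grid summary the greedy AIC search proved
bistable between near-tied optima, so the default summary model uses a
fixed light weight (0.01 in normalized units) — with k = 5 bases the
fitted surfaces are insensitive to the exact value, and the summary is
strictly deterministic.  Beta responses exactly on a boundary are shrunk
by (y(n−1)+0.5)/n with a warning.  Basis sizes: k = 5 for the simulation
summary, k = 3 for the case-study area model (deliberately small to avoid
over-fitting strongly autocorrelated covariates).  The fit was
cross-checked against an independent R implementation of the same family
(mgcv::gammals) on common data in the test suite.

## The scenario-grid experiment

All 25 (mean pattern × variance pattern) combinations are evaluated on a
common lattice of *t* values.  Per cell: evaluate (μ(t), σ²(t)), simulate
a session, fit one pooled OUF model, record H₉₅, effective sample size
and convergence.  Cells are seeded as (root, mean index, variance index,
time index), so any cell is rerunnable in isolation and rows are
independent.  Covariates are set exogenously by the scenario functions
and never updated from track outcomes.  Non-converged cells are dropped
(with a logged count) before the location-scale summary, which requires
at least 50 converged rows with genuine covariate spread.

Full-scale defaults are 200 tracks per cell and 50 lattice points; the
test suite and the acceptance script run the same design at 20–40 tracks
and 16–25 lattice points, which keeps each directional property
detectable in minutes on one CPU while leaving the study conditions
(scenario ranges, foraging constants, movement parameters) untouched.
The interaction and variance-surface checks use the largest of these
grids (20 tracks x 16 lattice points over all 25 scenario pairs): the
decile contrasts they evaluate sit in data-sparse corners of the
covariate cloud and need the extra replication to rise above
Monte-Carlo noise.

## The synthetic case study

The case study emulates, on generated data, the analysis template for one
range-resident tracked animal on a vegetation-index landscape (time in
days, coordinates in meters):

1. **NDVI rasters.**  A 15 × 15 grid over a 1 km square, 120 daily
   frames.  The mean field is a seasonal sinusoid (0.65 ± 0.2, period
   120 d) plus a gentle diagonal gradient; the variance field is a
   fraction q of the Beta bound μ(1−μ), with q = 0.08 ± 0.05 seasonal,
   phase-shifted a quarter period against the mean.  The quadrature phase
   keeps the two moments correlated-but-not-collinear over a season, so
   their effects remain separable; one independent Beta draw per cell and
   day; truth fields are retained for recovery tests.
2. **NDVI model.**  A Beta location-scale fit of the draws on smooths of
   time and the two coordinates (subsampled to 3,000 observations —
   the rasters vastly oversample the smooth surfaces).  On the default
   spec the fitted mean surface correlates with the generator truth at
   r ≈ 0.99 and the variance surface at r ≈ 0.97.
3. **Responsive track.**  A piecewise-stationary OUF track (τ_p = 8 h,
   τ_v ≈ 0.5 h, hourly fixes, 120 d) whose per-block positional variance
   follows ln ς² = ln(2500 m²) − 0.6·g + 0.4·h, with g and h the
   standardized local truth moments at the home-range center; blocks of
   3.5 days (half a window, so ς² is roughly constant within any window)
   are stitched continuously through the (position, velocity) state.
   The injected coefficients give a ~5-fold seasonal range swing —
   negative in the mean (less space when forage is rich), positive in
   the variance (more space when it is unpredictable); the interaction
   coefficient defaults to zero so the marginal directions are the
   recovery target.
4. **Windows.**  Left-aligned 7-day windows every 2 days (57 windows on
   120 d), each fitted with its own OUF model (OU fallback), converted to
   a Gaussian H₉₅, and kept only if the effective sample size reaches 7
   range crossings.  Window covariates are the unweighted averages of the
   estimated NDVI mean and variance at the window's fixes (bilinear in
   space, nearest day) — taken from the fitted Beta location-scale
   surfaces by default, with a truth-field mode to separate NDVI-model
   error from movement-model error in tests.
5. **Area model.**  Gamma location-scale fit of kept-window area on
   smooths of mean NDVI, NDVI variance and their tensor interaction, all
   with k = 3; at least 30 kept windows are required for the interaction
   model to be estimable.

Across 20 seeds of the full chain (fitted NDVI surfaces, not the truth
shortcut) the signs of both injected marginal effects were recovered 20
times in the test run.

What the generator does **not** emulate: perception, memory and resource
selection (space use responds only through the imposed response law),
NDVI retrieval artifacts (cloud, saturation, sensor noise), depletion,
competition or predation, multi-animal data, and geodesy (coordinates are
planar).  Passing tests therefore demonstrate that the estimation chain
recovers known mechanisms under its own assumptions — not that those
assumptions hold for any particular field system.

## Numerical choices, degenerate inputs, limitations

- Moment maps reject non-positive moments and Beta requests at or above
  the bound μ(1−μ), naming the bound.
- Scenario evaluation raises (naming the scenario and *t*) if a value is
  non-positive after clamping; deterministic kinds leave global RNG state
  untouched.
- The OUF autocovariance at τ_p = τ_v uses the analytic repeated-root
  limit; the filter guards the same degeneracy.
- Degenerate movement parameters yield −inf likelihood, never an
  exception; the optimizer treats them as hopeless.
- Posterior covariance matrices that fail positive-semidefiniteness by
  rounding are repaired by eigenvalue clipping, with a warning.
- Windows with fewer than 10 fixes, failed fits, or ESS < 7 are recorded
  with a reason, never silently dropped.
- Known limitations: home ranges are Gaussian-model areas (no kernel
  density estimation, no utilization-distribution rasters); the
  regression carries no explicit spatial or temporal autocorrelation
  terms (handled only by keeping bases small, as in the analysis pattern
  it mirrors); smoothing-parameter uncertainty is not propagated into the
  credible intervals; and the real-data path expects projected
  coordinates and user-supplied rasters.
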