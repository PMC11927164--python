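# stochrange

Simulation and estimation pipeline for a question in movement ecology: how
does the amount of space a foraging animal uses depend not only on how
*abundant* its resources are, but on how *unpredictable* they are?

Writing the resource supply at time *t* as a random variable *R* with mean
E(R) = μ(t) and variance Var(R) = σ²(t), the working hypotheses are that
home-range size *H* decreases nonlinearly with E(R) (a rich habitat needs
little searching; the classic *H = C/R* intuition, with *C* the consumption
target), increases nonlinearly with Var(R) (unpredictable returns force
longer searches), and that the two interact.  `stochrange` provides the
machinery to generate these patterns mechanistically, estimate them the way
a field analyst would, and run the same analysis template on telemetry plus
a vegetation-index raster series.  It is aimed at quantitative and movement
ecologists who work with continuous-time movement models and generalized
additive models.

## What is inside

- **`stochrange.resources`** — stochastic resource environments: temporal
  patterns for μ(t) and σ²(t) (constant, linear, cyclical, drifting,
  erratic), Gamma and Beta distributions parameterized directly by their
  moments (Gamma: shape = μ²/σ², scale = σ²/μ; Beta: α = μν, β = (1−μ)ν
  with ν = μ(1−μ)/σ² − 1), and an origin-anchored foraging grid.
- **`stochrange.movement`** — *exact* simulation of integrated
  Ornstein-Uhlenbeck (IOU), OU and OUF movement processes via the joint
  Gaussian transition of the (position, velocity) state (no Euler error),
  and satiety-truncated foraging: one Gamma draw per entry into a new grid
  cell, truncation once the cumulative collection reaches the satiety
  target *C*.
- **`stochrange.fitting`** — pooled maximum-likelihood fitting of OU / OUF /
  IOU models to track segments by a linear-time filtering likelihood
  (algebraically identical to the dense Gaussian process density), Wald
  intervals on log-scale parameters, and the Gaussian home-range area

      H_q = −2 ln(1 − q) · π · ς²,

  where ς² is the per-axis positional variance (H₉₅ ≈ 18.8227 ς²), plus the
  effective sample size (range crossings = duration / τ_p), crossing times
  and diffusion rates.
- **`stochrange.gamls`** — penalized location-scale regression (a compact
  GAMLSS): Gamma family (mean μ_H, scale s, Var = s μ_H²) for areas, Beta
  family (mean, precision φ) for NDVI-like indices; P-spline smooths with
  tensor-product interactions, Newton fitting with analytic derivatives,
  and multivariate-Gaussian posterior draws for credible intervals.
- **`stochrange.experiment`** — the 5 × 5 scenario grid (every mean pattern
  crossed with every variance pattern) over a time lattice: per cell, a
  session of IOU foraging tracks from a common origin, one pooled OUF fit,
  one H₉₅; then the Gamma location-scale summary of H on smooths of E(R),
  Var(R) and their interaction.
- **`stochrange.casestudy`** — a synthetic single-animal case study:
  Beta-distributed NDVI rasters with smoothly varying moments, a Beta
  location-scale model of those rasters, a range-resident track whose
  positional variance follows ln ς² = a + b·g(μ) + c·h(σ²) + d·g·h
  (defaults b < 0, c > 0), sliding 7-day window home ranges filtered at an
  effective sample size of ≥ 7 range crossings, and a k = 3 Gamma
  location-scale model of window area on the window's average NDVI mean,
  NDVI variance and their interaction.
- **`stochrange.io` / CLI** — Movebank-style telemetry reading, CSV result
  manifests, raster round-trips, YAML configs, and the `stochrange`
  command with `simulate`, `experiment`, `summarize`, `case-study` and
  `fit-telemetry` subcommands.

## Worked example

Fifty foraging tracks per condition, pooled OUF fit, Gaussian 95% area:

```python
import numpy as np
from stochrange import MomentPair, fit_movement_model, gaussian_home_range
from stochrange.experiment import default_design
from stochrange.movement import simulate_session

design = default_design(seed=0)
for mu, s2 in [(1.0, 4.0), (4.0, 4.0), (4.0, 36.0)]:
    rng = np.random.default_rng(42)
    segs = simulate_session(50, design.movement, design.grid,
                            MomentPair(mu, s2), design.foraging, rng,
                            design.dt)
    fit = fit_movement_model(segs, "OUF")
    n_cens = sum(s.censored for s in segs)
    print(f"E(R)={mu:>3}, Var(R)={s2:>4}:  H95 = "
          f"{gaussian_home_range(fit.sigma_position):6.1f}"
          f"  (censored tracks: {n_cens}/50)")
```

prints

```
E(R)=1.0, Var(R)= 4.0:  H95 =   52.6  (censored tracks: 16/50)
E(R)=4.0, Var(R)= 4.0:  H95 =   10.7  (censored tracks: 0/50)
E(R)=4.0, Var(R)=36.0:  H95 =   17.5  (censored tracks: 0/50)
```

Quadrupling the resource mean shrinks the home range roughly fivefold
(52.6 → 10.7 area units); at the richer mean, inflating the resource
variance ninefold pushes it back up (10.7 → 17.5), because highly skewed
resource draws stretch the search for satiety.  The censored count is the
number of tracks that hit the search-time ceiling before reaching satiety
— a third of the tracks in the poor habitat, none in the rich one.

The synthetic case study runs from the command line:

```sh
stochrange case-study --seed 3 --out results/case
```

which reports the number of 7-day windows, how many pass the
effective-sample-size filter, and the fitted log-area effects of mean NDVI
(negative: more space when forage is poor) and NDVI variance (positive:
more space when forage is unpredictable).

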