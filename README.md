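# camarray

Monte Carlo evaluation of camera-trap study designs: how many cameras per
site, and how long a season, does it take to detect a wildlife species
reliably?

Camera-trap surveys routinely boost low detection probabilities with baits
or non-random camera placement, both of which bias downstream occupancy and
abundance estimates. An alternative is a *camera array*: a cluster of
several randomly placed cameras within each site. `camarray` quantifies the
detectability returns of array size (1–10 cameras per site) and season
length (1–365 days) by repeatedly parsing a yearlong detection dataset into
hypothetical smaller designs, the way such data are analysed in practice:

- **Independence rule.** Raw trigger events of a species at a site are
  merged whenever successive events fall within 30 minutes of each other,
  *across all cameras in the site* — a raccoon passing two neighbouring
  cameras ten minutes apart is one detection.
- **Survey detectability `p = ΣP/(Nk)`.** Each Monte Carlo
  iteration draws an array size *m*, a season window and a replicate length
  *L* (1–28 days); the season is cut into `k = ⌊S/L⌋` replicates and *p* is
  the fraction of detected (site × replicate) cells, with occupancy assumed
  to be 1 so zeros are detection failures, not absences.
- **Season detectability `p* = 1 − (1 − p)^k`.** The chance of at least one
  detection over a whole season.
- **Saturation curve `p* = A(1 − e^(−RS))`.** Fitted per species × array
  size by bounded nonlinear least squares with 95% confidence intervals;
  its inverse `S = −ln(1 − p*/A)/R` gives the minimum season length for a
  target detectability, the core of the design calculator.
- **Array-size inference.** All-pairs comparisons of per-draw *p* between
  array sizes with heteroscedasticity-robust standard errors, single-step
  max-|t| familywise adjustment (or a max-statistic permutation test), and
  a compact letter display.

Because field datasets of this kind are rarely shared, the package includes
a first-class synthetic-data generator that emulates the clustered field
design (4 sites × two 1-ha clusters of 5 cameras, ~65 m within-cluster and
~589 m between-cluster spacing, yearlong deployment) with per-camera-day
Poisson encounters, log-normal camera heterogeneity, seasonal modulation,
and short-lag companion events that exercise the 30-minute rule.

## Worked example

```python
import datetime as dt
from camarray import (DEFAULT_SPECIES_MODELS, DesignConfig, generate_deployment,
                      simulate_events, run_monte_carlo, summarize_by_array_size,
                      fit_by_design)

deployment = generate_deployment(seed=1)            # 40 cameras, 4 sites
events = simulate_events(deployment, DEFAULT_SPECIES_MODELS, seed=2)
mc = run_monte_carlo(events, deployment, DesignConfig(array_sizes=(1, 2, 3, 5, 10)),
                     n_iterations=1000, master_seed=3,
                     year_start=dt.date(2015, 1, 1))
print(summarize_by_array_size(mc))
```

For the rare, strongly camera-heterogeneous species ("bobcat") this prints

```
            p_mean  p_q50
array_size
1            0.062  0.028
2            0.143  0.100
3            0.199  0.167
5            0.293  0.283
10           0.533  0.583
```

— a second camera more than doubles mean survey detectability, whereas the
common species ("deer", not shown) is already at `p ≈ 0.98` with one
camera. Fitting the season curves and inverting them:

```python
fits = fit_by_design(mc)
print(fits[fits.species_id == "bobcat"][["array_size", "A_hat", "R_hat"]])
```

```
 array_size  A_hat  R_hat
          1 1.0000 0.0030
          2 0.8223 0.0119
          3 0.9257 0.0144
          5 0.9830 0.0203
         10 0.9997 0.0475
```

so a two-camera bobcat array reaches a season detectability of 0.4 after
about 56 days, while a single camera needs more than five months. The
`examples/` directory has one short script per capability (simulation,
deduplication, Monte Carlo subsampling, curve fitting, array comparison,
and the 40-cameras/90-days design-planning scenario), each printing the
numbers it computes and what they mean. A thin CLI wraps the same
functions: `camarray run-all --config run.yaml --seed 1 --out outdir`
(stages are also available individually: `simulate`, `dedup`, `subsample`,
`fit`, `compare`, `scenario`).

A useful benchmark built into the formulas: the commonly recommended
minimum survey detectability of 0.15 combined with a three-replicate design
gives a season detectability of `1 − 0.85³ ≈ 0.39`.

## Layout

```
src/camarray/     synthetic, events, subsampling, detectability,
                  curvefit, comparison, pipeline, io, cli
examples/         one narrative script per capability
tests/            pytest suite with brute-force oracles and property tests
docs/methods.md   models, assumptions, parameter choices, limitations
```
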