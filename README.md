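# wolfallee

Allee-effect analysis for a recolonizing gray-wolf population.

Small, recovering carnivore populations can show an **Allee effect**:
per-capita growth that *increases* with population size at low density,
because components of fitness such as mate-finding fail when
conspecifics are sparse.  A *strong* demographic Allee effect means
growth is negative below a threshold population size, putting a young
population at direct risk of extinction.  This package implements a
complete pipeline for detecting and explaining such effects in a
wolf-recolonization setting, for population ecologists and
conservation modellers:

1. **Detector** (`wolfallee.spline_detector`) — a Bayesian penalized
   low-rank thin-plate spline for the relationship between per-capita
   growth rate, `pgr_t = ln(N_t / N_{t-1})`, and log population size
   `ln N_t`:

       pgr_t ~ Normal(mu_t, sigma^2),
       mu_t = beta0 + beta ln N_t + sum_k alpha_k Z_k(ln N_t),

   with vague priors (`beta ~ N(0, 100^2)`, `alpha_k ~ N(0, nu^2)`,
   `nu, sigma ~ U(0, 100)`), fit by blocked Gibbs sampling with
   Gelman-Rubin convergence checks.  A hump-shaped posterior curve is
   evidence of a demographic Allee effect; its upward zero-crossing is
   the Allee threshold.
2. **Simulator** (`wolfallee.ibse_simulator`) — an individual-based,
   spatially explicit annual-cycle wolf model (mate-finding within a
   perception neighborhood of 1-5 territories, lognormal winter/fall
   dispersal, territorial packs of up to 10, spatial mortality risk,
   targeted lethal control) on a synthetic landscape with exactly 363
   candidate 225-km² territories, 151 of them in the Wisconsin region.
3. **Classifier** (`wolfallee.trajectory_classifier`) — reduces each
   simulated trajectory to extinct / strong Allee / weak Allee / no
   evidence via a six-knot smoothing spline of growth versus log size.
4. **Scenario regression** (`wolfallee.scenario_regression`) — Bayesian
   logistic regression of Allee probability on the perception x
   dispersal design.

Synthetic generators (`wolfallee.synthetic_data`) provide abundance
series with a known Allee threshold and calibrated landscapes, so the
entire pipeline runs and validates with no external data.

## Worked example

Detect the Allee threshold in a synthetic 35-year recovery series whose
true threshold is 30 animals:

```python
from wolfallee import SplineConfig, compute_growth, sample_posterior, summarize_allee
from wolfallee.synthetic_data import AlleeGeneratorParams, benchmark_series

series, truth = benchmark_series(AlleeGeneratorParams(seed=0))
fit = sample_posterior(
    compute_growth(series),
    SplineConfig(n_iter=20_000, n_burnin=5_000, thin=10, seed=0),
)
summary = summarize_allee(fit, series, force=True)
print(summary.shape, summary.strength)
thr = summary.allee_threshold
print(f"threshold {thr.abundance:.1f} (95% CrI {thr.ci_low:.1f}-{thr.ci_high:.1f})")
```

prints

```
monotone_increasing strong
threshold 21.2 (95% CrI 16.1-43.4)
```

— fitted growth is negative below an estimated threshold of ~21 animals
(a strong Allee effect), and the 95% credible interval (16-43) covers
the generator's true threshold of 30; the point estimate sits low
because a surviving recovery series over-represents lucky growth at low
abundance.  The curve's falling branch was too weakly sampled for a
credible hump call in this realization, so the shape is reported as
monotone increasing.

The full analysis is organised as numbered drivers:

```bash
python analysis/01_detect_demographic_allee.py 1     # detector demo / real data
python analysis/02_simulate_scenarios.py 1 25        # 15 scenarios x 25 reps
python analysis/03_classify_outcomes.py              # outcome table
python analysis/04_regress_allee_probability.py 1    # posterior Allee probability
```

`03_classify_outcomes.py` ends with, for example:

```
375 repetitions: 0.0% extinct, 55.7% with a probable Allee effect
of 14 strong-Allee outcomes: 71.4% at perception 1, 78.6% under high dispersal
```

— strong Allee effects concentrate where wolves can only sense mates
one territory away and disperse far, the mate-finding mechanism the
scenario design probes.  The detector stage on the four published census
measures needs the supplementary census tables transcribed into
`data/<measure>.csv` (year,count); without them the drivers fall back to
synthetic series.

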