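# primesim

Comparative risk assessment macro-simulation of diet-attributable
cardiovascular and cancer mortality.

Public-health analysts often need to know how many deaths a population
would avoid in a year if dietary intake met national recommendations —
more fruit and vegetables, more fiber, less salt, a better fat profile —
and which recommendation matters most. Trials cannot answer this at
population scale, so the standard tool is a macro-simulation: contrast the
observed (baseline) intake distributions with a counterfactual population
whose mean intakes meet the recommendations while within-population
variance is unchanged, push the contrast through dose-response relative
risks, and convert it into deaths prevented or delayed against registry
mortality. This package implements that model for a Sweden-like setting:
nine dietary components, nine ICD-10 cause-of-death groups (CVD and
diet-related cancers), sex/age stratification, and Monte Carlo uncertainty
intervals.

## The model in brief

For exposure level x, risk follows a log-linear dose-response
RR(x) = exp(β·(min(x, x_cap) − x₀)) with β = ln(RR_inc)/Δ, capped at the
threshold x_cap above which no further benefit accrues; BMI instead
follows a J-shaped (log-quadratic) curve. Salt, fats and energy act
through mediators (systolic blood pressure, serum cholesterol, BMI).
Population risk is the expectation E[RR(X)] over the stratum's intake
distribution; the potential impact fraction of a counterfactual shift is

    PIF = (E_base[RR] − E_cf[RR]) / E_base[RR],

pathway PIFs combine multiplicatively — combined = 1 − Π(1 − vᵢ), so a 12%
and a 10% reduction give 20.8%, never more than 100% — and deaths averted
are PIF × observed deaths, summed over strata. Uncertainty comes from
5000-iteration Monte Carlo (every ln RR, mediation slope and intake mean
varies by its standard error), reported as 2.5th–97.5th percentile
intervals. See `docs/methods.md` for assumptions, numerical choices and
limitations.

**Dose-response parameters are placeholders.** The meta-analysis values
behind published national estimates are not bundled; the shipped parameter
file carries plausible, clearly tagged placeholder values, and every
report computed from them says so. Absolute outputs characterise the
pipeline, not any country.

## Worked example

```bash
python analysis/01_build_inputs.py --seed 0     # writes results/inputs/
python analysis/02_point_estimates.py           # deterministic run
python analysis/03_monte_carlo.py --n-iter 300  # uncertainty intervals
python analysis/04_attribution_shares.py        # attribution shares
```

The point-estimate step prints (placeholder parameters, synthetic
registry table conserving the published 2016 Swedish class totals):

```
                       Scenario  Men Women Total Men share (%) Women share (%)
          Fruits and vegetables 1538  1060  2598            46              44
                          Fiber  679   831  1510            20              34
                           Fats  649   542  1191            19              22
                           Salt  858   221  1079            26               9
All dietary guidelines combined 3344  2436  5780

combined scenario: 5780 deaths prevented or delayed (19.5% of in-scope mortality)
```

Each row is one counterfactual: the named components' means move to their
recommended targets (fruits 250 g/day, fiber 30 g/day, salt 6 g/day, ...)
with variance preserved, everything else stays at baseline. The combined
row is less than the sum of the others — multiplicative combination makes
joint benefit subadditive. Shares are each scenario's deaths averted
relative to the combined scenario within sex. The Monte Carlo step adds
95% uncertainty intervals per cell, e.g. `1536 (1141-1907)` for fruits and
vegetables among men at 300 iterations.

The same pipeline is scriptable from a shell via the `primesim` CLI
(`validate`, `synth`, `simulate`, `mc`, `report`) or directly from Python:

```python
from primesim.synthetic import default_configuration
from primesim.scenarios import baseline_scenario, build_component_scenarios, default_targets
from primesim.simulate import run_monte_carlo, summarize

config = default_configuration(seed=0)
scenarios = build_component_scenarios(
    baseline_scenario(config), default_targets(config.components))
result = run_monte_carlo(config, scenarios, n_iter=1000, seed=0)
print(summarize(result, "component_by_sex"))
```

## Layout

```
src/primesim/        library: domain model, risk mathematics, scenarios,
                     simulation engine, synthetic data, io, CLI
analysis/            numbered narrative drivers writing results/
tests/               pytest suite (unit, property and end-to-end checks)
scripts/acceptance.py  headline quantities as JSON
docs/methods.md      model description, assumptions, limitations
```
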