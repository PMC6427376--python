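# Methods

## The model

`primesim` implements a comparative risk assessment (CRA) macro-simulation
for diet and mortality. It answers one question: how many cause-specific
deaths would be prevented or delayed in a single year if a population's
dietary intake distributions shifted from their observed means to
recommended targets, with everything else held fixed?

The population is stratified by sex and age band. Each stratum carries, per
dietary component, a parametric intake distribution summarised by its mean
and SD, and per cause of death a registry-style death count. The model
assumptions are:

1. **Log-linear dose-response.** The relative risk of death from cause *d*
   at exposure level *x* is

   RR(x) = exp(β · (min(x, x_cap) − x₀)),   β = ln(RR_inc) / Δ,

   where RR_inc is the relative risk per increment Δ of exposure, x₀ a
   reference level, and x_cap an upper threshold above which no further
   change in risk accrues (reflecting the exposure range of the underlying
   meta-analyses). Moving from 2 to 3 daily servings therefore changes risk
   by the same factor as moving from 7 to 8, until the cap.

2. **J-shaped BMI curve.** Adiposity is the one exception to log-linearity:
   RR(BMI) = exp(c_side · (BMI − nadir)²), equal to 1 at the nadir and
   rising on both sides with side-specific curvature c (ln RR per
   (kg/m²)²). This is the minimal smooth parameterisation of a J shape;
   nothing in the pipeline depends on the exact form beyond RR(nadir) = 1
   and monotone wings.

3. **Mediated pathways.** Some exposures act through intermediate
   biological risk factors: salt through systolic blood pressure (mmHg),
   fat composition and dietary cholesterol through serum total cholesterol
   (mmol/L), energy through BMI (kg/m²). A mediation parameter is a linear
   slope (mediator units per exposure unit); the mediator shift
   slope · Δμ for a population mean change Δμ is pushed through the
   mediator-scale RR. Mediated effects are evaluated at the stratum's mean
   shift (a scalar per stratum), whereas direct dietary pathways are
   integrated over the full intake distribution — mediator distributions
   within strata are not modelled, only their mean displacement.

4. **Multiplicative combination.** Risk changes v_i from simultaneous
   changes combine as 1 − Π(1 − v_i): survival fractions multiply. The
   joint benefit is therefore less than the sum of its parts and can never
   exceed a 100% reduction. A 12% and a 10% reduction jointly give 20.8%.

5. **Counterfactual = mean shift, variance preserved.** The counterfactual
   population has each selected component's mean at the recommended target
   and the within-population SD (and distribution family) unchanged.
   Because distributions are moment-parameterised, the shift is a
   re-solve of the family parameters for (target mean, old SD) — for the
   gamma family this keeps support strictly positive with no truncated
   mass, which a sample translation would not.

## Population risk and deaths averted

Population risk is the expectation of the individual RR over the stratum's
intake distribution, **E[RR(X)]**, not RR evaluated at the mean intake.
This is the standard CRA construction and the reason the
variance-preservation assumption matters at all: for log-linear RR and a
normal exposure, E[RR(X)] = exp(β(μ − x₀) + β²σ²/2), so the σ term is
common to baseline and counterfactual and cancels in the ratio — the
potential impact fraction under a pure mean shift is exactly
1 − exp(βΔμ) — but with a cap, or a non-normal family, the variance does
not cancel.

The potential impact fraction for one pathway is

PIF = (E_base[RR] − E_cf[RR]) / E_base[RR],

pathway PIFs for one cause are combined multiplicatively (assumption 4),
and the combined proportional reduction times the stratum's observed
deaths gives deaths prevented or delayed, summed over strata to sex level.
The point-estimate engine is exactly additive: Total = Men + Women in
every cell.

## Numerical choices

- **Quadrature.** E[RR(X)] uses adaptive quadrature
  (`scipy.integrate.quad`, absolute tolerance 1e-8) over the distribution's
  support intersected with mean ± 12 SD (truncated mass < 1e-30; the
  window prevents the adaptive rule from missing a distribution that is
  narrow relative to an infinite domain). A capped parameter splits the
  integral at the cap and adds RR(cap) times the survival mass, keeping the
  integrand smooth. If the adaptive rule still warns, a 64-point
  Gauss-Legendre rule on mean ± 8 SD is used. Integrands use hand-written
  scalar pdfs (normal/lognormal/gamma) because generic frozen-distribution
  calls dominate quadrature cost. Expectations are memoised on the frozen
  (distribution, parameter) pair.
- **Distribution families.** Quantity components (g/day, mg/day, kJ/day)
  default to gamma (guaranteed positivity); %E components to normal. The
  lognormal family is available. Family parameters are always re-solved
  from (mean, SD) by moment inversion.
- **Degenerate inputs.** SD → 0 collapses E[RR(X)] to RR(mean) within the
  quadrature tolerance; empty risk-change lists combine to zero change; a
  cap at or below the support floor returns RR(cap) exactly.
- **Tie-breaks and rounding.** Report counts and percentages round half
  away from zero (floor(x + 0.5)), matching the convention of the printed
  tables this pipeline's output mimics.
- **Increments.** RR increments may be negative ("RR 0.95 per 2 mmHg
  decrease"); only zero is rejected. Shipped files use positive increments.

## Monte Carlo uncertainty

Every uncertain quantity varies per draw: ln RR ~ Normal(ln RR_inc,
se_lnRR), mediation slope ~ Normal(slope, se), and each stratum's baseline
intake mean ~ Normal(mean, SE) with SE = SD/√n from the survey. Mortality
counts are registry totals, treated as exhaustive rather than sampled.
Targets stay fixed; each draw rebuilds the baseline and re-derives every
counterfactual, re-running the whole pipeline. Draw *i* uses the spawned
substream `SeedSequence(seed, spawn_key=(i,))`, so results are independent
of execution order and bit-reproducible given (seed, n_iter). Quantities
with zero SE are reused without resampling, so a degenerate run reproduces
the deterministic configuration exactly. The 95% uncertainty interval is
the empirical 2.5th–97.5th percentile range with the linear-interpolation
quantile definition; the reported central value is the mean over draws
(the deterministic point estimate is reported alongside). The production
default is 5000 iterations; bundled drivers and tests use 300–1000, which
this pipeline's interval widths do not visibly change.

## Dose-response parameters are placeholders

The dose-response magnitudes that would reproduce any published national
estimate come from an external meta-analysis compilation and are not
bundled. The shipped parameter file carries literature-plausible
placeholder values, every record tagged `"provenance": "placeholder"`; the
engine propagates that tag into results and the report renderer prints an
explicit notice. Absolute outputs of the default run characterise the
pipeline, not Sweden. The file is plain JSON and is meant to be edited
with sourced values.

## Synthetic data

The real inputs — survey microdata and registry counts — are not publicly
deposited, so the package generates stand-ins:

- **Survey generator.** Per sex, n individuals (792 men, 1005 women by
  default) with one value per component. Margins follow each component's
  family with moments (published mean, SD = SE·√n); within-person
  dependence between fruits, vegetables and fiber uses a Gaussian copula
  (default pairwise 0.4; the dependence is real but unquantified in the
  source material, so it is configurable). The latent Gaussian scores are
  standardised per component before the margin transform: the generator's
  contract is to emulate a survey whose *printed summary statistics* are
  the targets, so sample moments match the targets tightly instead of
  scattering with full iid noise. Consequences: generated tables are
  slightly "too good" relative to a real survey redraw, and the generator
  does not emulate non-response bias, reporting error, or the
  significance-test structure of the source table — passing tests say the
  pipeline handles data *shaped* like the survey, not that survey-specific
  biases are captured.
- **Mortality generator.** Published sex totals per disease class are
  split across causes with fixed plausible proportions and across age
  bands with an exponential age gradient (counts double per decade of band
  midpoint), using largest-remainder integer apportionment so the
  published totals are conserved exactly and counts rise with age. The
  cause-level split within each class is an assumption — the registry
  publishes class totals only in the material this emulates.
- **Miniature fixture.** A 2-band, 3-component (fruits, fiber, salt),
  2-cause (CHD, stroke) configuration that exercises every pathway type
  (capped direct, uncapped direct, mediated) and runs the full pipeline in
  well under a second.

## Scope and limitations

- Single-year, mortality-only: no time-to-benefit lags, no multi-year
  projection, no morbidity or quality-adjusted outcomes.
- Pathway independence is assumed up to multiplicative combination; shared
  biology between components (fiber in fruit, for instance) can double
  count benefit.
- The energy→BMI J-shape pathway is implemented and tested but inactive in
  the default configuration, which carries no energy intake rows; it
  activates when energy data, an energy→BMI slope, a J-shape record and a
  baseline BMI are all supplied.
- Whether intake caps apply before or after the counterfactual shift is a
  genuine modelling choice; here the cap lives inside the RR function
  (an intake-space clamp applied in both scenarios).
- Age banding of the default configuration is a single 18–81 band per sex
  (the published intake summary is not age-stratified); the machinery
  supports arbitrary disjoint bands and the synthetic generators default
  to decade bands.
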