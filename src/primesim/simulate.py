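"""Simulation engine: point-estimate runs, component attribution and Monte
Carlo uncertainty intervals.

For every (cause, stratum) cell the engine contrasts the baseline and
counterfactual population-average relative risks pathway by pathway,
combines the resulting proportional risk changes multiplicatively, converts
the combined change to deaths prevented or delayed against the stratum's
observed mortality, and aggregates over strata to sex-level outputs.

Uncertainty propagates by re-running that whole pipeline under parameter
draws: every ln RR, mediation slope and intake mean varies according to its
reported standard error. Draws use one root seed with a counter-based
per-draw substream, so results do not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .domain import (
    CAUSES,
    DiseaseClass,
    IntakeDistribution,
    Mediator,
    ModelConfiguration,
    PopulationStratum,
    Sex,
)
from .risk import (
    RiskChange,
    combine_risk_changes,
    deaths_averted,
    jshape_risk_at,
    mediated_risk_at,
    population_average_rr,
    potential_impact_fraction,
)
from .scenarios import ALL_LABEL, Scenario, baseline_scenario, build_counterfactual

__all__ = [
    "ScenarioResult",
    "ParameterDraw",
    "make_parameter_draw",
    "apply_parameter_draw",
    "run_point_estimate",
    "run_monte_carlo",
    "summarize",
    "component_shares",
    "round_half_up",
]

ResultKey = tuple[str, str, str]  # (scenario label, cause id, sex)


@dataclass
class ScenarioResult:
    """Deaths averted/delayed by (scenario, cause, sex) with uncertainty.

    ``point`` holds the deterministic estimate. After a Monte Carlo run,
    ``mean`` is the mean over draws, ``lower``/``upper`` the empirical 2.5th
    and 97.5th percentiles, and ``draws`` the full per-draw vectors (kept so
    that derived aggregates — totals over sexes or causes — can be
    percentiled correctly rather than by summing percentiles).
    """

    point: dict[ResultKey, float]
    mean: Optional[dict[ResultKey, float]] = None
    lower: Optional[dict[ResultKey, float]] = None
    upper: Optional[dict[ResultKey, float]] = None
    draws: Optional[dict[ResultKey, np.ndarray]] = None
    n_iterations: int = 1
    seed: Optional[int] = None
    provenance: str = "unspecified"

    def scenario_labels(self) -> list[str]:
        seen: list[str] = []
        for (label, _, _) in self.point:
            if label not in seen:
                seen.append(label)
        return seen

    def causes(self) -> list[str]:
        return sorted({cause for (_, cause, _) in self.point})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScenarioResult):
            return NotImplemented
        if (
            self.point != other.point
            or self.mean != other.mean
            or self.lower != other.lower
            or self.upper != other.upper
            or self.n_iterations != other.n_iterations
            or self.seed != other.seed
        ):
            return False
        if (self.draws is None) != (other.draws is None):
            return False
        if self.draws is not None:
            if set(self.draws) != set(other.draws):
                return False
            return all(
                np.array_equal(self.draws[k], other.draws[k]) for k in self.draws
            )
        return True

    @classmethod
    def merge(cls, results: Sequence["ScenarioResult"]) -> "ScenarioResult":
        """Concatenate results for disjoint scenario labels."""
        merged = cls(point={}, provenance=results[0].provenance if results else "unspecified")
        for res in results:
            merged.point.update(res.point)
            for attr in ("mean", "lower", "upper", "draws"):
                src = getattr(res, attr)
                if src is not None:
                    dst = getattr(merged, attr) or {}
                    dst.update(src)
                    setattr(merged, attr, dst)
            merged.n_iterations = max(merged.n_iterations, res.n_iterations)
            if res.seed is not None:
                merged.seed = res.seed
        return merged

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: scenario, cause, sex, point[, mean, lower, upper]."""
        rows = []
        for key, value in self.point.items():
            label, cause, sex = key
            row = {"scenario": label, "cause": cause, "sex": sex, "point": value}
            if self.mean is not None:
                row["mean"] = self.mean[key]
                row["lower"] = self.lower[key]
                row["upper"] = self.upper[key]
            rows.append(row)
        return pd.DataFrame(rows)


def _stratum_risk_changes(
    config: ModelConfiguration,
    baseline: Scenario,
    scenario: Scenario,
    cause: str,
    stratum: PopulationStratum,
) -> list[RiskChange]:
    """All per-exposure risk changes for one (cause, stratum) cell."""
    changes: list[RiskChange] = []
    for comp in config.components:
        b = baseline.distributions[(comp, stratum)]
        c = scenario.distributions[(comp, stratum)]
        if c.mean == b.mean and c.sd == b.sd:
            continue  # component untouched in this scenario
        # Direct dose-response pathway.
        param = config.relative_risks.get((comp, cause))
        if param is not None:
            eb = population_average_rr(b, param, scenario="baseline")
            ec = population_average_rr(c, param, scenario="counterfactual")
            pif = potential_impact_fraction(eb, ec)
            changes.append(RiskChange(pif, source=comp, cause=cause))
        # Mediated pathways: the population mean shift moves the mediator.
        for (source, mediator), med in config.mediations.items():
            if source != comp:
                continue
            delta_mu = c.mean - b.mean
            if mediator is Mediator.BMI and cause in config.jshapes:
                js = config.jshapes[cause]
                bmi0 = config.baseline_bmi[stratum]
                ratio = jshape_risk_at(bmi0 + med.slope * delta_mu, js)
                ratio /= jshape_risk_at(bmi0, js)
                changes.append(
                    RiskChange(1.0 - ratio, source=f"{comp}->bmi", cause=cause)
                )
            else:
                rr_m = config.relative_risks.get((mediator.value, cause))
                if rr_m is not None:
                    ratio = mediated_risk_at(delta_mu, med, rr_m)
                    changes.append(
                        RiskChange(
                            1.0 - ratio,
                            source=f"{comp}->{mediator.value}",
                            cause=cause,
                        )
                    )
    return changes


def run_point_estimate(
    config: ModelConfiguration,
    scenario: Scenario,
    baseline: Optional[Scenario] = None,
) -> ScenarioResult:
    """Deterministic deaths averted for one scenario.

    Per-stratum combined risk changes are applied to that stratum's
    mortality and summed to sex level, so Total = Men + Women holds exactly
    for any downstream aggregation of this result.
    """
    if baseline is None:
        baseline = baseline_scenario(config)
    point: dict[ResultKey, float] = {}
    for cause in config.mortality.causes():
        by_sex = {sex: 0.0 for sex in Sex}
        for stratum in config.strata:
            deaths = config.mortality.deaths(cause, stratum)
            if deaths == 0:
                continue
            changes = _stratum_risk_changes(config, baseline, scenario, cause, stratum)
            combined = combine_risk_changes(changes)
            by_sex[stratum.sex] += deaths_averted(combined.value, deaths)
        for sex in Sex:
            point[(scenario.label, cause, sex.value)] = by_sex[sex]
    return ScenarioResult(point=point, provenance=config.provenance)


@dataclass(frozen=True)
class ParameterDraw:
    """One Monte Carlo realisation of every uncertain quantity.

    Fully determined by (seed, draw_index): draw ``i`` uses the spawned
    substream ``SeedSequence(seed, spawn_key=(i,))`` regardless of how many
    other draws ran before it.
    """

    ln_rr: Mapping[tuple[str, str], float]
    slopes: Mapping[tuple[str, str], float]
    intake_means: Mapping[tuple[str, PopulationStratum], float]
    draw_index: int
    seed: int


def make_parameter_draw(
    config: ModelConfiguration,
    seed: int,
    draw_index: int,
    vary_intake_means: bool = True,
) -> ParameterDraw:
    """Draw ln RRs, mediation slopes and intake means for one iteration.

    ln RR ~ Normal(ln rr_per_increment, ln_rr_se); slope ~ Normal(slope,
    slope_se); intake mean ~ Normal(mean, se) with se = sd / sqrt(n).
    Quantities with zero SE are reproduced exactly (no resampling noise, no
    exp/log round trip). Mortality counts are registry totals and are not
    sampled.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(draw_index,)))
    ln_rr = {}
    for key in sorted(config.relative_risks):
        p = config.relative_risks[key]
        ln_rr[key] = float(rng.normal(math.log(p.rr_per_increment), p.ln_rr_se))
    slopes = {}
    for key in sorted(config.mediations, key=lambda k: (k[0], k[1].value)):
        m = config.mediations[key]
        slopes[(key[0], key[1].value)] = float(rng.normal(m.slope, m.slope_se))
    intake_means = {}
    for key in sorted(
        config.intakes, key=lambda k: (k[0], k[1].sex.value, k[1].age_band)
    ):
        d = config.intakes[key]
        if vary_intake_means:
            mean = float(rng.normal(d.mean, d.se))
            # Keep support valid for positive families; intake SEs are tiny
            # relative to the mean so this floor is essentially never active.
            intake_means[key] = max(mean, 1e-9)
        else:
            intake_means[key] = d.mean
    return ParameterDraw(
        ln_rr=ln_rr,
        slopes=slopes,
        intake_means=intake_means,
        draw_index=draw_index,
        seed=seed,
    )


def apply_parameter_draw(
    config: ModelConfiguration, draw: ParameterDraw
) -> ModelConfiguration:
    """Realise one draw as a new frozen configuration.

    Records whose SE is zero are reused as-is so a degenerate draw
    reproduces the deterministic configuration bit for bit.
    """
    new_rr = {
        key: (
            p
            if p.ln_rr_se == 0.0
            else replace(p, rr_per_increment=math.exp(draw.ln_rr[key]))
        )
        for key, p in config.relative_risks.items()
    }
    new_med = {
        key: (
            m
            if m.slope_se == 0.0
            else replace(m, slope=draw.slopes[(key[0], key[1].value)])
        )
        for key, m in config.mediations.items()
    }
    new_intakes = {
        key: (
            d
            if draw.intake_means[key] == d.mean
            else replace(d, mean=draw.intake_means[key])
        )
        for key, d in config.intakes.items()
    }
    return ModelConfiguration(
        intakes=new_intakes,
        mortality=config.mortality,
        relative_risks=new_rr,
        mediations=new_med,
        jshapes=config.jshapes,
        baseline_bmi=config.baseline_bmi,
        meta=config.meta,
    )


def _scenario_recipe(scenario: Scenario) -> tuple[frozenset[str], dict[str, float]]:
    """Recover (active components, targets) so a scenario can be rebuilt on
    top of a perturbed baseline. Counterfactual means are identical across
    strata by construction, so any stratum yields the target."""
    targets: dict[str, float] = {}
    for (comp, _), dist in scenario.distributions.items():
        if comp in scenario.active_components and comp not in targets:
            targets[comp] = dist.mean
    return scenario.active_components, targets


def run_monte_carlo(
    config: ModelConfiguration,
    scenarios: Sequence[Scenario],
    n_iter: int = 5000,
    seed: int = 0,
    vary_intake_means: bool = True,
) -> ScenarioResult:
    """Monte Carlo uncertainty intervals over ``n_iter`` parameter draws.

    Each draw re-runs the full pipeline: the baseline is rebuilt from the
    drawn intake means and every counterfactual is re-derived on top of it
    (targets stay fixed at the recommendations). The 95% uncertainty
    interval is the empirical 2.5th-97.5th percentile range
    (linear-interpolation quantile definition); the reported central value
    is the mean over draws. Bit-reproducible given (seed, n_iter).
    """
    if n_iter < 2:
        raise ValueError(f"n_iter must be >= 2, got {n_iter}")
    recipes = [( s.label, *_scenario_recipe(s)) for s in scenarios]

    point_parts = [run_point_estimate(config, s) for s in scenarios]
    point = ScenarioResult.merge(point_parts).point

    draws: dict[ResultKey, np.ndarray] = {
        key: np.empty(n_iter) for key in point
    }
    for i in range(n_iter):
        draw = make_parameter_draw(config, seed, i, vary_intake_means=vary_intake_means)
        perturbed = apply_parameter_draw(config, draw)
        pbase = baseline_scenario(perturbed)
        for label, active, targets in recipes:
            cf = build_counterfactual(pbase, targets, active, label=label)
            res = run_point_estimate(perturbed, cf, baseline=pbase)
            for key, value in res.point.items():
                draws[key][i] = value

    mean = {key: float(np.mean(v)) for key, v in draws.items()}
    lower = {
        key: float(np.quantile(v, 0.025, method="linear"))
        for key, v in draws.items()
    }
    upper = {
        key: float(np.quantile(v, 0.975, method="linear"))
        for key, v in draws.items()
    }
    return ScenarioResult(
        point=point,
        mean=mean,
        lower=lower,
        upper=upper,
        draws=draws,
        n_iterations=n_iter,
        seed=seed,
        provenance=config.provenance,
    )


def round_half_up(x: float) -> int:
    """Round halves away from zero toward +inf (reporting convention)."""
    return math.floor(x + 0.5)


def component_shares(
    estimates: Mapping[tuple[str, str], float], combined_label: str = ALL_LABEL
) -> dict[tuple[str, str], int]:
    """Share of each scenario's deaths averted, as integer percentages.

    The denominator is the combined all-recommendations scenario within the
    same sex (shares therefore need not sum to 100 because the combined
    effect is subadditive). Keys are (scenario label, sex).
    """
    sexes = sorted({sex for (_, sex) in estimates})
    shares: dict[tuple[str, str], int] = {}
    for sex in sexes:
        denom = estimates.get((combined_label, sex))
        if denom is None:
            denom = sum(
                v for (label, s), v in estimates.items() if s == sex
            )
        if denom == 0:
            continue
        for (label, s), value in estimates.items():
            if s != sex or label == combined_label:
                continue
            shares[(label, sex)] = round_half_up(100.0 * value / denom)
    return shares


def _aggregate(
    result: ScenarioResult, keys: Sequence[ResultKey]
) -> tuple[float, Optional[float], Optional[float]]:
    """Central value and UI for a sum over result cells.

    With draws available the per-draw vectors are summed first and the mean
    and percentiles taken on the summed vector.
    """
    if result.draws is not None:
        total = np.zeros(result.n_iterations)
        for key in keys:
            total += result.draws[key]
        return (
            float(np.mean(total)),
            float(np.quantile(total, 0.025, method="linear")),
            float(np.quantile(total, 0.975, method="linear")),
        )
    return sum(result.point[k] for k in keys), None, None


def _fmt_cell(central: float, lo: Optional[float], hi: Optional[float]) -> str:
    if lo is None:
        return f"{round_half_up(central)}"
    return f"{round_half_up(central)} ({round_half_up(lo)}-{round_half_up(hi)})"


def summarize(
    result: ScenarioResult,
    level: str = "component_by_sex",
    mortality=None,
    all_label: str = ALL_LABEL,
) -> pd.DataFrame:
    """Report tables in the standard two shapes.

    ``component_by_sex``: one row per scenario, Men/Women/Total columns
    ("central (lower-upper)" when Monte Carlo draws are present), plus
    per-sex share-of-total percentage columns.

    ``cause_by_sex``: one row per cause of death for the combined scenario,
    grouped CVD first then cancer, with actual-mortality rows appended when
    a mortality table is supplied.
    """
    sexes = [Sex.MALE.value, Sex.FEMALE.value]
    if level == "component_by_sex":
        rows = []
        central_by = {}
        for label in result.scenario_labels():
            cells = {}
            for sex in sexes:
                keys = [
                    k for k in result.point if k[0] == label and k[2] == sex
                ]
                cells[sex] = _aggregate(result, keys)
                central_by[(label, sex)] = cells[sex][0]
            total_keys = [k for k in result.point if k[0] == label]
            cells["total"] = _aggregate(result, total_keys)
            rows.append((label, cells))
        shares = component_shares(central_by, combined_label=all_label)
        records = []
        for label, cells in rows:
            records.append(
                {
                    "Scenario": label,
                    "Men": _fmt_cell(*cells["male"]),
                    "Women": _fmt_cell(*cells["female"]),
                    "Total": _fmt_cell(*cells["total"]),
                    "Men share (%)": shares.get((label, "male"), ""),
                    "Women share (%)": shares.get((label, "female"), ""),
                }
            )
        return pd.DataFrame.from_records(records)

    if level == "cause_by_sex":
        label = all_label if all_label in result.scenario_labels() else result.scenario_labels()[-1]
        records = []
        for disease_class in (DiseaseClass.CVD, DiseaseClass.CANCER):
            for cause in result.causes():
                if CAUSES[cause].disease_class is not disease_class:
                    continue
                cells = {}
                for sex in sexes:
                    cells[sex] = _aggregate(result, [(label, cause, sex)])
                cells["total"] = _aggregate(
                    result, [(label, cause, s) for s in sexes]
                )
                records.append(
                    {
                        "Cause": cause,
                        "Class": disease_class.value,
                        "Men": _fmt_cell(*cells["male"]),
                        "Women": _fmt_cell(*cells["female"]),
                        "Total": _fmt_cell(*cells["total"]),
                    }
                )
            if mortality is not None:
                men = mortality.total(disease_class=disease_class, sex=Sex.MALE)
                women = mortality.total(disease_class=disease_class, sex=Sex.FEMALE)
                records.append(
                    {
                        "Cause": "Actual mortality",
                        "Class": disease_class.value,
                        "Men": str(men),
                        "Women": str(women),
                        "Total": str(men + women),
                    }
                )
        return pd.DataFrame.from_records(records)

    raise ValueError(f"unknown summary level {level!r}")
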