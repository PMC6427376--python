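"""Engine behaviour: point estimates, attribution, Monte Carlo contracts."""

import math
from dataclasses import replace

import numpy as np
import pytest

from primesim.domain import (
    AgeBand,
    DistributionFamily,
    IntakeDistribution,
    MortalityTable,
    PopulationStratum,
    RelativeRiskParameter,
    Sex,
    validate_configuration,
)
from primesim.scenarios import (
    ALL_LABEL,
    baseline_scenario,
    build_counterfactual,
    build_component_scenarios,
    default_targets,
)
from primesim.simulate import (
    ScenarioResult,
    component_shares,
    round_half_up,
    run_monte_carlo,
    run_point_estimate,
    summarize,
)


def _single_pathway_config(family=DistributionFamily.NORMAL, deaths=1000):
    """One stratum, one cause, one direct uncapped parameter."""
    stratum = PopulationStratum(Sex.MALE, AgeBand(18, 81))
    dist = IntakeDistribution("fruits", stratum, mean=105.0, sd=30.0, n=100, family=family)
    mortality = MortalityTable(entries={("chd", stratum): deaths})
    param = RelativeRiskParameter(
        exposure="fruits", cause="chd", rr_per_increment=0.93, increment=100.0
    )
    return validate_configuration([dist], mortality, [param])


def test_null_counterfactual_averts_no_deaths(fixture_config):
    baseline = baseline_scenario(fixture_config)
    null = build_counterfactual(baseline, {}, [], label="null")
    res = run_point_estimate(fixture_config, null, baseline)
    assert all(v == 0.0 for v in res.point.values())


def test_single_pathway_matches_hand_computed_chain():
    """One normal exposure, uncapped log-linear RR: deaths averted equal
    (1 - exp(beta * delta_mu)) * deaths, the closed-form PIF chain."""
    config = _single_pathway_config(deaths=1000)
    baseline = baseline_scenario(config)
    cf = build_counterfactual(baseline, {"fruits": 250.0}, ["fruits"], label="cf")
    res = run_point_estimate(config, cf, baseline)
    beta = math.log(0.93) / 100.0
    expected = (1.0 - math.exp(beta * 145.0)) * 1000
    assert res.point[("cf", "chd", "male")] == pytest.approx(expected, rel=1e-7)
    assert res.point[("cf", "chd", "female")] == 0.0


def test_combined_scenario_is_subadditive(fixture_config, fixture_scenarios):
    baseline, scenarios = fixture_scenarios
    parts = [run_point_estimate(fixture_config, s, baseline) for s in scenarios]
    merged = ScenarioResult.merge(parts)
    isolated = [s.label for s in scenarios if s.label != ALL_LABEL]
    for cause in merged.causes():
        for sex in ("male", "female"):
            combined = merged.point[(ALL_LABEL, cause, sex)]
            total = sum(merged.point[(lab, cause, sex)] for lab in isolated)
            assert combined <= total + 1e-9
            assert combined >= 0.0


def test_doubling_mortality_doubles_deaths_averted(fixture_config, fixture_scenarios):
    baseline, scenarios = fixture_scenarios
    doubled_mort = MortalityTable(
        entries={k: 2 * v for k, v in fixture_config.mortality.entries.items()},
        reference_year=fixture_config.mortality.reference_year,
    )
    doubled = replace(fixture_config, mortality=doubled_mort)
    res1 = run_point_estimate(fixture_config, scenarios[-1], baseline)
    res2 = run_point_estimate(doubled, scenarios[-1], baseline)
    for key, v in res1.point.items():
        assert res2.point[key] == pytest.approx(2.0 * v, rel=1e-12)


def test_deaths_averted_bounded_by_cause_mortality(fixture_config, fixture_scenarios):
    baseline, scenarios = fixture_scenarios
    res = run_point_estimate(fixture_config, scenarios[-1], baseline)
    for (label, cause, sex), v in res.point.items():
        observed = fixture_config.mortality.total(cause=cause, sex=Sex(sex))
        assert v <= observed + 1e-9


def test_enlarging_a_beneficial_shift_never_reduces_benefit():
    config = _single_pathway_config()
    baseline = baseline_scenario(config)
    values = []
    for target in (150.0, 200.0, 250.0, 300.0):
        cf = build_counterfactual(baseline, {"fruits": target}, ["fruits"], label="cf")
        values.append(run_point_estimate(config, cf, baseline).point[("cf", "chd", "male")])
    assert values == sorted(values)


class TestMonteCarlo:
    def test_rejects_single_iteration(self, fixture_config, fixture_scenarios):
        _, scenarios = fixture_scenarios
        with pytest.raises(ValueError):
            run_monte_carlo(fixture_config, scenarios[:1], n_iter=1, seed=0)

    def test_zero_uncertainty_collapses_interval(self, fixture_config, fixture_scenarios):
        """With every SE zero the 95% UI degenerates onto the point estimate."""
        _, scenarios = fixture_scenarios
        cfg = replace(
            fixture_config,
            relative_risks={
                k: replace(p, ln_rr_se=0.0)
                for k, p in fixture_config.relative_risks.items()
            },
            mediations={
                k: replace(m, slope_se=0.0)
                for k, m in fixture_config.mediations.items()
            },
        )
        res = run_monte_carlo(
            cfg, scenarios[:2], n_iter=50, seed=1, vary_intake_means=False
        )
        for key, point in res.point.items():
            assert res.lower[key] == res.upper[key]
            # summation of identical draws can differ by 1 ulp
            assert res.mean[key] == pytest.approx(res.lower[key], rel=1e-14)
            assert res.mean[key] == pytest.approx(point, rel=1e-12)

    def test_same_seed_is_bit_identical(self, fixture_config, fixture_scenarios):
        _, scenarios = fixture_scenarios
        a = run_monte_carlo(fixture_config, scenarios[:2], n_iter=40, seed=11)
        b = run_monte_carlo(fixture_config, scenarios[:2], n_iter=40, seed=11)
        c = run_monte_carlo(fixture_config, scenarios[:2], n_iter=40, seed=12)
        assert a == b
        assert a != c

    def test_percentiles_match_sort_based_oracle(self, fixture_config, fixture_scenarios):
        _, scenarios = fixture_scenarios
        res = run_monte_carlo(fixture_config, scenarios[:2], n_iter=97, seed=5)
        for key, v in res.draws.items():
            s = np.sort(v)
            for q, stored in ((0.025, res.lower[key]), (0.975, res.upper[key])):
                h = (len(s) - 1) * q
                lo = math.floor(h)
                oracle = s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
                assert stored == pytest.approx(oracle, abs=1e-9)

    def test_point_estimate_falls_inside_interval(self, fixture_config, fixture_scenarios):
        _, scenarios = fixture_scenarios
        res = run_monte_carlo(fixture_config, scenarios, n_iter=150, seed=2)
        inside = [
            res.lower[k] <= res.point[k] <= res.upper[k]
            for k in res.point
            if res.upper[k] > 0
        ]
        assert sum(inside) / len(inside) >= 0.95


class TestSummaries:
    def test_component_shares_normalise_against_combined(self):
        estimates = {
            ("A", "male"): 30.0,
            ("B", "male"): 30.0,
            (ALL_LABEL, "male"): 50.0,
        }
        shares = component_shares(estimates)
        assert shares == {("A", "male"): 60, ("B", "male"): 60}

    def test_rounding_is_half_up(self):
        assert round_half_up(52.5) == 53
        assert round_half_up(19.4999) == 19
        assert round_half_up(9.5) == 10

    def test_totals_equal_men_plus_women_in_point_table(
        self, fixture_config, fixture_scenarios
    ):
        baseline, scenarios = fixture_scenarios
        merged = ScenarioResult.merge(
            [run_point_estimate(fixture_config, s, baseline) for s in scenarios]
        )
        table = summarize(merged, "component_by_sex")
        for _, row in table.iterrows():
            assert int(row["Total"]) == pytest.approx(
                int(row["Men"]) + int(row["Women"]), abs=1
            )

    def test_cause_table_lists_cvd_then_cancer_with_actual_mortality(
        self, fixture_config, fixture_scenarios
    ):
        baseline, scenarios = fixture_scenarios
        merged = ScenarioResult.merge(
            [run_point_estimate(fixture_config, s, baseline) for s in scenarios]
        )
        table = summarize(
            merged, "cause_by_sex", mortality=fixture_config.mortality
        )
        assert list(table["Cause"])[-1] == "Actual mortality" or "Actual mortality" in set(table["Cause"])
        men = fixture_config.mortality.total(sex=Sex.MALE)
        mort_rows = table[table["Cause"] == "Actual mortality"]
        assert sum(int(v) for v in mort_rows["Men"]) == men
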