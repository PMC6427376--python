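"""Dose-response, combination and population-expectation mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from primesim.domain import (
    AgeBand,
    DistributionFamily,
    IntakeDistribution,
    JShapeParameter,
    MediationParameter,
    PopulationStratum,
    RelativeRiskParameter,
    Sex,
)
from primesim.errors import ChainingError
from primesim.risk import (
    PopulationRisk,
    RiskChange,
    combine_risk_changes,
    deaths_averted,
    jshape_risk_at,
    mediated_risk_at,
    population_average_rr,
    potential_impact_fraction,
    relative_risk_at,
)

STRATUM = PopulationStratum(Sex.MALE, AgeBand(18, 81))


def _rr(rr=0.88, increment=1.0, ref=0.0, cap=None, cause="chd", exposure="fruits"):
    return RelativeRiskParameter(
        exposure=exposure,
        cause=cause,
        rr_per_increment=rr,
        increment=increment,
        reference_level=ref,
        cap_level=cap,
    )


def _dist(mean, sd, family=DistributionFamily.NORMAL, n=100):
    return IntakeDistribution("fruits", STRATUM, mean=mean, sd=sd, n=n, family=family)


class TestRelativeRisk:
    def test_identity_at_reference(self):
        assert relative_risk_at(3.0, _rr(ref=3.0)) == pytest.approx(1.0)

    def test_two_increments_square_the_per_increment_risk(self):
        # RR 0.88 per serving, two servings above reference
        assert relative_risk_at(2.0, _rr(0.88)) == pytest.approx(0.7744, abs=1e-12)

    def test_equal_changes_give_equal_risk_ratios(self):
        # moving from 2 to 3 servings changes RR by the same factor as 7 to 8
        p = _rr(0.88, cap=10.0)
        low = relative_risk_at(3.0, p) / relative_risk_at(2.0, p)
        high = relative_risk_at(8.0, p) / relative_risk_at(7.0, p)
        assert low == pytest.approx(high, rel=1e-12)

    @given(
        st.floats(0.0, 20.0),
        st.floats(0.0, 20.0),
        st.floats(0.0, 5.0),
        st.floats(0.6, 1.5).filter(lambda r: abs(r - 1) > 1e-3),
    )
    def test_log_linearity(self, x1, x2, delta, rr):
        p = _rr(rr, cap=100.0)
        r1 = relative_risk_at(x1 + delta, p) / relative_risk_at(x1, p)
        r2 = relative_risk_at(x2 + delta, p) / relative_risk_at(x2, p)
        assert r1 == pytest.approx(r2, rel=1e-12)

    @given(st.floats(0.0, 50.0))
    def test_cap_idempotence(self, extra):
        """Intake beyond the cap confers no further change in risk."""
        p = _rr(0.9, cap=5.0)
        assert relative_risk_at(5.0 + extra, p) == relative_risk_at(5.0, p)


class TestJShape:
    P = JShapeParameter("chd", nadir=22.5, curvature_below=0.002, curvature_above=0.002)

    def test_unit_risk_at_nadir(self):
        assert jshape_risk_at(22.5, self.P) == 1.0

    def test_log_quadratic_value(self):
        assert jshape_risk_at(27.5, self.P) == pytest.approx(math.exp(0.05), rel=1e-12)

    def test_monotone_away_from_nadir_on_both_sides(self):
        above = [jshape_risk_at(22.5 + d, self.P) for d in (1, 2, 4, 8)]
        below = [jshape_risk_at(22.5 - d, self.P) for d in (1, 2, 4, 8)]
        assert all(b > a >= 1.0 for a, b in zip(above, above[1:])) or above == sorted(above)
        assert above == sorted(above) and below == sorted(below)
        assert min(above + below) > 1.0


class TestMediatedRisk:
    MED = MediationParameter("salt", "systolic_bp", slope=1.0)
    RRM = _rr(0.95, increment=-2.0, exposure="systolic_bp")

    def test_no_intake_change_is_neutral(self):
        assert mediated_risk_at(0.0, self.MED, self.RRM) == pytest.approx(1.0)

    def test_salt_reduction_through_blood_pressure(self):
        # 2.84 g/day less salt -> 2.84 mmHg lower systolic BP; RR 0.95 per
        # 2 mmHg reduction -> 0.95**1.42
        val = mediated_risk_at(-2.84, self.MED, self.RRM)
        assert val == pytest.approx(math.exp(math.log(0.95) * 2.84 / 2), rel=1e-12)
        assert val == pytest.approx(0.9297, abs=1e-4)

    def test_slope_increment_rescaling_invariance(self):
        """Doubling the mediation slope while halving the RR increment is a
        pure reparameterisation."""
        med2 = MediationParameter("salt", "systolic_bp", slope=2.0)
        rr_half = _rr(0.95, increment=-1.0, exposure="systolic_bp")
        a = mediated_risk_at(-1.7, med2, self.RRM)
        b = mediated_risk_at(-1.7, self.MED, rr_half)
        assert a == pytest.approx(b, rel=1e-12)

    def test_mediator_mismatch_raises(self):
        rr_direct = _rr(0.95, exposure="serum_cholesterol")
        with pytest.raises(ChainingError):
            mediated_risk_at(-1.0, self.MED, rr_direct)


class TestCombination:
    def test_worked_example(self):
        """12% and 10% reductions jointly reduce risk by 20.8%."""
        combined = combine_risk_changes(
            [RiskChange(0.12, "vegetables", "chd"), RiskChange(0.10, "salt", "chd")]
        )
        assert combined.value == pytest.approx(0.208, abs=1e-12)

    def test_empty_combination_is_no_change(self):
        assert combine_risk_changes([]).value == 0.0

    def test_three_halvings(self):
        changes = [RiskChange(0.5, s, "chd") for s in "abc"]
        assert combine_risk_changes(changes).value == pytest.approx(0.875, abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_bounds_and_subadditivity(self, values):
        changes = [RiskChange(v, str(i), "chd") for i, v in enumerate(values)]
        out = combine_risk_changes(changes).value
        assert 0.0 <= out <= 1.0
        assert out <= sum(values) + 1e-12
        assert out >= max(values) - 1e-12

    @given(st.permutations([0.12, 0.10, 0.3, 0.05]))
    def test_order_invariance(self, perm):
        changes = [RiskChange(v, str(i), "chd") for i, v in enumerate(perm)]
        ref = combine_risk_changes(
            [RiskChange(v, str(i), "chd") for i, v in enumerate([0.12, 0.10, 0.3, 0.05])]
        )
        assert combine_risk_changes(changes).value == pytest.approx(
            ref.value, rel=1e-12
        )

    def test_risk_change_cannot_exceed_full_reduction(self):
        with pytest.raises(ValueError):
            RiskChange(1.5, "fruits", "chd")


class TestPopulationAverage:
    def test_degenerate_distribution_at_reference(self):
        d = _dist(mean=3.0, sd=1e-9)
        out = population_average_rr(d, _rr(0.9, ref=3.0))
        # quadrature contract is 1e-8 absolute
        assert out.mean_rr == pytest.approx(1.0, abs=1e-7)

    def test_matches_normal_moment_formula(self):
        """E[exp(beta(X - x0))] = exp(beta(mu - x0) + beta^2 sigma^2 / 2)."""
        d = _dist(mean=105.0, sd=40.0)
        p = _rr(0.93, increment=100.0, ref=50.0)
        beta = math.log(0.93) / 100.0
        expected = math.exp(beta * (105.0 - 50.0) + beta**2 * 40.0**2 / 2.0)
        out = population_average_rr(d, p)
        assert out.mean_rr == pytest.approx(expected, rel=1e-9)

    def test_capped_expectation_matches_sampling(self):
        """Quadrature with a cap agrees with a large microdata sample."""
        rng = np.random.default_rng(42)
        d = _dist(mean=105.0, sd=60.0, family=DistributionFamily.GAMMA)
        p = _rr(0.90, increment=100.0, ref=0.0, cap=180.0)
        x = d.frozen().rvs(size=400_000, random_state=rng)
        rr = np.exp(p.beta * (np.minimum(x, 180.0) - 0.0))
        mc_mean, mc_se = rr.mean(), rr.std(ddof=1) / math.sqrt(len(rr))
        out = population_average_rr(d, p)
        assert abs(out.mean_rr - mc_mean) < 3 * mc_se


class TestPIF:
    def test_null_counterfactual(self):
        d = _dist(105.0, 30.0)
        p = _rr(0.93, increment=100.0)
        b = population_average_rr(d, p, scenario="baseline")
        c = population_average_rr(d, p, scenario="counterfactual")
        assert potential_impact_fraction(b, c) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sigma", [5.0, 20.0, 60.0])
    def test_pure_mean_shift_is_variance_free(self, sigma):
        """For a normal exposure and uncapped log-linear RR the PIF equals
        1 - exp(beta * delta_mu); the variance terms cancel."""
        p = _rr(0.93, increment=100.0)
        beta = math.log(0.93) / 100.0
        b = population_average_rr(_dist(105.0, sigma), p, "baseline")
        c = population_average_rr(_dist(250.0, sigma), p, "counterfactual")
        assert potential_impact_fraction(b, c) == pytest.approx(
            1.0 - math.exp(beta * 145.0), rel=1e-8
        )

    def test_beneficial_shift_has_nonnegative_pif(self):
        p = _rr(0.9, increment=100.0, cap=400.0)
        b = population_average_rr(_dist(105.0, 40.0), p, "baseline")
        c = population_average_rr(_dist(250.0, 40.0), p, "counterfactual")
        pif = potential_impact_fraction(b, c)
        assert 0.0 <= pif <= 1.0

    def test_requires_matching_cause(self):
        b = PopulationRisk(1.2, "chd", "baseline")
        c = PopulationRisk(1.0, "stroke", "counterfactual")
        with pytest.raises(ValueError):
            potential_impact_fraction(b, c)


class TestDeathsAverted:
    @pytest.mark.parametrize(
        "pif,deaths,expected", [(0.0, 500, 0.0), (0.1, 1000, 100.0), (1.0, 1000, 1000.0)]
    )
    def test_scaling(self, pif, deaths, expected):
        assert deaths_averted(pif, deaths) == pytest.approx(expected)

    def test_never_exceeds_observed_deaths(self):
        assert deaths_averted(1.0, 1234) <= 1234
        with pytest.raises(ValueError):
            deaths_averted(1.2, 100)
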