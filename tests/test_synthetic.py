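"""Synthetic survey and registry generators: moments, positivity,
conservation, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from primesim.domain import DiseaseClass, Sex
from primesim.io import load_configuration
from primesim.scenarios import baseline_scenario, build_counterfactual, default_targets
from primesim.simulate import run_point_estimate
from primesim.synthetic import (
    DEFAULT_CANCER_TOTALS,
    DEFAULT_CVD_TOTALS,
    DEFAULT_INTAKE_SUMMARY,
    SyntheticMortalitySpec,
    apportion,
    default_mortality_spec,
    default_survey_spec,
    generate_intake_survey,
    generate_mortality_table,
    make_test_fixture,
    summarize_survey,
)


class TestSurvey:
    def test_sample_moments_track_the_published_summary(self):
        """Per-sex sample means land near the targets (the sampling SD of
        the mean is exactly the published SE) and sample SDs recover
        se * sqrt(n) within 15%."""
        records = generate_intake_survey(default_survey_spec(seed=20))
        for (comp, sex), (mean, se, n) in DEFAULT_INTAKE_SUMMARY.items():
            values = records.loc[records["sex"] == sex, comp]
            assert len(values) == n
            assert abs(values.mean() - mean) < 4.0 * se
            target_sd = se * math.sqrt(n)
            assert abs(values.std(ddof=1) - target_sd) < 0.15 * target_sd

    def test_quantity_components_are_strictly_positive(self):
        records = generate_intake_survey(default_survey_spec(seed=3))
        for comp in ("fruits", "vegetables", "fiber", "salt", "cholesterol"):
            assert (records[comp] > 0).all()

    def test_same_seed_reproduces_records_exactly(self):
        a = generate_intake_survey(default_survey_spec(seed=9))
        b = generate_intake_survey(default_survey_spec(seed=9))
        c = generate_intake_survey(default_survey_spec(seed=10))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)
        assert list(a.columns) == list(c.columns)

    def test_correlated_components_are_positively_associated(self):
        records = generate_intake_survey(default_survey_spec(seed=4))
        men = records[records["sex"] == "male"]
        rho = np.corrcoef(men["fruits"], men["vegetables"])[0, 1]
        assert rho > 0.2
        rho_indep = np.corrcoef(men["salt"], men["fruits"])[0, 1]
        assert abs(rho_indep) < 0.1

    def test_summary_round_trip(self):
        records = generate_intake_survey(default_survey_spec(seed=5))
        dists = summarize_survey(records)
        by_key = {(d.component, d.stratum.sex.value): d for d in dists}
        mean, se, n = DEFAULT_INTAKE_SUMMARY[("fiber", "male")]
        assert by_key[("fiber", "male")].mean == pytest.approx(mean, abs=4 * se)


class TestApportionment:
    @given(
        st.integers(0, 100000),
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=12),
    )
    def test_exact_conservation(self, total, weights):
        counts = apportion(total, weights)
        assert counts.sum() == total
        assert (counts >= 0).all()

    def test_mortality_totals_conserved_exactly(self):
        table = generate_mortality_table(default_mortality_spec())
        for sex, expected in DEFAULT_CVD_TOTALS.items():
            assert table.total(DiseaseClass.CVD, Sex(sex)) == expected
        for sex, expected in DEFAULT_CANCER_TOTALS.items():
            assert table.total(DiseaseClass.CANCER, Sex(sex)) == expected

    def test_counts_rise_with_age_under_default_gradient(self):
        table = generate_mortality_table(default_mortality_spec())
        for cause in ("chd", "stroke"):
            for sex in Sex:
                counts = [
                    deaths
                    for (c, stratum), deaths in sorted(
                        table.entries.items(), key=lambda kv: kv[0][1].age_band
                    )
                    if c == cause and stratum.sex is sex
                ]
                assert counts == sorted(counts)

    def test_zero_deaths_spec_gives_all_zero_table(self):
        spec = SyntheticMortalitySpec(
            totals={("chd", "male"): 0, ("chd", "female"): 0}
        )
        table = generate_mortality_table(spec)
        assert all(v == 0 for v in table.entries.values())


class TestFixture:
    def test_fixture_validates_and_runs_in_under_a_second(self, fixture_config):
        assert fixture_config.mortality.total() > 0

    def test_all_components_run_averts_deaths(self, fixture_config):
        """With benefit-direction-consistent placeholder risks, shifting
        every component toward its recommendation saves lives."""
        baseline = baseline_scenario(fixture_config)
        cf = build_counterfactual(
            baseline,
            default_targets(fixture_config.components),
            fixture_config.components,
            label="all",
        )
        res = run_point_estimate(fixture_config, cf, baseline)
        assert all(v > 0 for v in res.point.values())

    def test_two_seeds_differ_but_share_schema(self, tmp_path):
        p1 = make_test_fixture(1, tmp_path / "a")
        p2 = make_test_fixture(2, tmp_path / "b")
        intake1 = p1[0].read_text().splitlines()
        intake2 = p2[0].read_text().splitlines()
        assert intake1[0] == intake2[0]  # identical header
        assert intake1[1:] != intake2[1:]  # different microdata
        cfg1 = load_configuration(*p1)
        cfg2 = load_configuration(*p2)
        assert cfg1.components == cfg2.components
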