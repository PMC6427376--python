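"""Synthetic survey microdata and registry-style mortality tables.

The real inputs — a national dietary survey's individual records and
cause-of-death registry counts — are not publicly deposited, so this module
generates stand-ins with the statistical structure the analysis assumes:
per-sex intake margins matching published summary statistics (mean, SE, n)
with a Gaussian copula for within-person correlation between related
components, and cause x sex x age-band death counts that conserve the
published sex totals per disease class exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .domain import (
    CAUSES,
    AgeBand,
    DistributionFamily,
    DiseaseClass,
    IntakeDistribution,
    MortalityTable,
    PopulationStratum,
    Sex,
    default_family,
    gamma_params,
    lognormal_params,
)
from .errors import FeasibilityError

__all__ = [
    "SyntheticSurveySpec",
    "SyntheticMortalitySpec",
    "DEFAULT_INTAKE_SUMMARY",
    "DEFAULT_CVD_TOTALS",
    "DEFAULT_CANCER_TOTALS",
    "default_survey_spec",
    "default_mortality_spec",
    "default_intake_distributions",
    "apportion",
    "generate_intake_survey",
    "summarize_survey",
    "generate_mortality_table",
    "make_test_fixture",
]

#: Published per-sex intake summaries for Sweden (survey 2010-11):
#: (component, sex) -> (mean, SE of mean, n). Units follow the component
#: registry.
DEFAULT_INTAKE_SUMMARY: Mapping[tuple[str, str], tuple[float, float, int]] = {
    ("fruits", "male"): (105.0, 3.97, 792),
    ("fruits", "female"): (147.0, 3.53, 1005),
    ("vegetables", "male"): (169.0, 3.69, 792),
    ("vegetables", "female"): (182.0, 3.09, 1005),
    ("fiber", "male"): (21.30, 0.29, 792),
    ("fiber", "female"): (18.80, 0.22, 1005),
    ("salt", "male"): (8.84, 0.10, 792),
    ("salt", "female"): (6.78, 0.063, 1005),
    ("total_fat", "male"): (34.0, 0.21, 792),
    ("total_fat", "female"): (34.40, 0.20, 1005),
    ("saturated_fat", "male"): (13.0, 0.11, 792),
    ("saturated_fat", "female"): (13.10, 0.10, 1005),
    ("mufa", "male"): (12.80, 0.09, 792),
    ("mufa", "female"): (12.90, 0.09, 1005),
    ("pufa", "male"): (5.5, 0.067, 792),
    ("pufa", "female"): (5.7, 0.06, 1005),
    ("cholesterol", "male"): (320.0, 5.15, 792),
    ("cholesterol", "female"): (263.0, 3.9, 1005),
}

#: Registry deaths in the reference year (2016), by sex, for the disease
#: classes in scope.
DEFAULT_CVD_TOTALS: Mapping[str, int] = {"male": 12206, "female": 11093}
DEFAULT_CANCER_TOTALS: Mapping[str, int] = {"male": 3251, "female": 3141}

#: Cause-level splits within each disease class. The registry publishes the
#: class totals; these fixed proportions are a plausible decomposition
#: (ischaemic heart disease dominant within CVD, lung above colorectal
#: within the diet-related cancers).
DEFAULT_CAUSE_SPLIT: Mapping[str, float] = {
    "chd": 0.45,
    "stroke": 0.28,
    "heart_failure": 0.10,
    "hypertensive": 0.08,
    "aortic_aneurysm": 0.05,
    "pulmonary_embolism": 0.03,
    "rheumatic_heart": 0.01,
    "colorectal_cancer": 0.45,
    "lung_cancer": 0.55,
}


@dataclass(frozen=True)
class SyntheticSurveySpec:
    """Targets for survey emulation.

    ``rows`` maps (component, sex) -> (mean, se, n); all components within
    one sex must share the same n (one questionnaire per person).
    ``correlation`` lists pairwise within-person correlations on the
    Gaussian-copula scale; unlisted pairs are independent.
    """

    rows: Mapping[tuple[str, str], tuple[float, float, int]]
    families: Mapping[str, DistributionFamily] = field(default_factory=dict)
    correlation: Mapping[frozenset, float] = field(
        default_factory=lambda: {
            frozenset({"fruits", "vegetables"}): 0.4,
            frozenset({"fruits", "fiber"}): 0.4,
            frozenset({"vegetables", "fiber"}): 0.4,
        }
    )
    age_range: tuple[int, int] = (18, 80)
    seed: int = 0

    def __post_init__(self) -> None:
        for (comp, sex), (mean, se, n) in self.rows.items():
            if n <= 0:
                raise FeasibilityError(f"n must be positive for ({comp}, {sex})")
            if se <= 0:
                raise FeasibilityError(f"se must be positive for ({comp}, {sex})")
            if mean <= 0:
                raise FeasibilityError(f"mean must be positive for ({comp}, {sex})")

    def components(self) -> list[str]:
        return sorted({c for (c, _) in self.rows})

    def family(self, component: str) -> DistributionFamily:
        return self.families.get(component, default_family(component))

    def sample_size(self, sex: str) -> int:
        ns = {n for (c, s), (_, _, n) in self.rows.items() if s == sex}
        if len(ns) != 1:
            raise FeasibilityError(
                f"all components must share one sample size per sex, got {ns}"
            )
        return ns.pop()


@dataclass(frozen=True)
class SyntheticMortalitySpec:
    """Targets for registry emulation.

    ``totals`` maps (cause, sex) -> deaths; ``age_doubling_decades`` sets
    the default exponential age gradient (counts double every this many
    decades of the band midpoint).
    """

    totals: Mapping[tuple[str, str], int]
    age_bands: tuple[AgeBand, ...] = tuple(
        AgeBand(lo, hi)
        for lo, hi in [(18, 25), (25, 35), (35, 45), (45, 55), (55, 65), (65, 75), (75, 121)]
    )
    age_doubling_decades: float = 1.0
    reference_year: int = 2016
    seed: int = 0

    def __post_init__(self) -> None:
        for (cause, sex), deaths in self.totals.items():
            if cause not in CAUSES:
                raise FeasibilityError(f"unknown cause {cause!r}")
            if deaths < 0:
                raise FeasibilityError("death totals must be >= 0")


def default_survey_spec(seed: int = 0) -> SyntheticSurveySpec:
    return SyntheticSurveySpec(rows=DEFAULT_INTAKE_SUMMARY, seed=seed)


def default_mortality_spec(seed: int = 0) -> SyntheticMortalitySpec:
    """Class totals split across causes with the default proportions.

    The split is apportioned by largest remainder so the published sex
    totals per disease class are conserved exactly.
    """
    totals: dict[tuple[str, str], int] = {}
    for disease_class, class_totals in (
        (DiseaseClass.CVD, DEFAULT_CVD_TOTALS),
        (DiseaseClass.CANCER, DEFAULT_CANCER_TOTALS),
    ):
        causes = [
            c for c in CAUSES.values() if c.disease_class is disease_class
        ]
        weights = np.array([DEFAULT_CAUSE_SPLIT[c.id] for c in causes])
        for sex, total in class_totals.items():
            counts = apportion(total, weights)
            for cause, count in zip(causes, counts):
                totals[(cause.id, sex)] = int(count)
    return SyntheticMortalitySpec(totals=totals, seed=seed)


def default_intake_distributions(
    age_band: AgeBand = AgeBand(18, 81),
) -> list[IntakeDistribution]:
    """The published summary table as model-ready distributions (one age
    band per sex; sd reconstructed as se * sqrt(n))."""
    dists = []
    for (comp, sex), (mean, se, n) in DEFAULT_INTAKE_SUMMARY.items():
        stratum = PopulationStratum(Sex(sex), age_band)
        dists.append(
            IntakeDistribution(
                component=comp,
                stratum=stratum,
                mean=mean,
                sd=se * math.sqrt(n),
                n=n,
                family=default_family(comp),
            )
        )
    return dists


def apportion(total: int, weights: Sequence[float]) -> np.ndarray:
    """Largest-remainder integer apportionment: nonnegative integers that
    sum to ``total`` exactly, proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if total == 0:
        return np.zeros(len(weights), dtype=int)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with a positive sum")
    quotas = total * weights / weights.sum()
    counts = np.floor(quotas).astype(int)
    remainder = int(round(total - counts.sum()))
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _margin_ppf(u: np.ndarray, mean: float, sd: float, family: DistributionFamily):
    if family is DistributionFamily.NORMAL:
        return stats.norm.ppf(u, loc=mean, scale=sd)
    if family is DistributionFamily.LOGNORMAL:
        mu, sigma = lognormal_params(mean, sd)
        return stats.lognorm.ppf(u, s=sigma, scale=math.exp(mu))
    k, theta = gamma_params(mean, sd)
    return stats.gamma.ppf(u, a=k, scale=theta)


def _correlation_matrix(spec: SyntheticSurveySpec, comps: list[str]) -> np.ndarray:
    k = len(comps)
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho = spec.correlation.get(frozenset({comps[i], comps[j]}), 0.0)
            corr[i, j] = corr[j, i] = rho
    # Guard: the user-supplied matrix must be positive definite.
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise FeasibilityError("correlation matrix is not positive definite") from exc
    return corr


def generate_intake_survey(
    spec: SyntheticSurveySpec, seed: Optional[int] = None
) -> pd.DataFrame:
    """Individual-level intake records (one row per person).

    Margins follow each component's family with moments (mean, sd =
    se * sqrt(n)); dependence between components comes from a Gaussian
    copula. The latent Gaussian scores are standardised per component
    before the margin transform, so the generated sample reproduces the
    published summary moments tightly (the generator's contract is to
    emulate a survey whose printed table IS those statistics) instead of
    scattering around them with full sampling noise. Reproducible from the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    comps = spec.components()
    frames = []
    person = 0
    for sex in (Sex.MALE.value, Sex.FEMALE.value):
        n = spec.sample_size(sex)
        corr = _correlation_matrix(spec, comps)
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n, len(comps))) @ chol.T
        # column-wise moment matching on the latent scale
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
        u = ndtr(z)
        # keep ppf arguments strictly inside (0, 1)
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        data = {
            "person_id": np.arange(person, person + n),
            "sex": sex,
            "age": rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n),
        }
        for j, comp in enumerate(comps):
            mean, se, n_c = spec.rows[(comp, sex)]
            sd = se * math.sqrt(n_c)
            data[comp] = _margin_ppf(u[:, j], mean, sd, spec.family(comp))
        frames.append(pd.DataFrame(data))
        person += n
    return pd.concat(frames, ignore_index=True)


def summarize_survey(
    records: pd.DataFrame,
    age_bands: Sequence[AgeBand] = (AgeBand(18, 81),),
) -> list[IntakeDistribution]:
    """Collapse microdata to per-stratum (mean, sd, n) summaries."""
    comps = [c for c in records.columns if c not in ("person_id", "sex", "age")]
    out = []
    for sex in records["sex"].unique():
        for band in age_bands:
            sub = records[
                (records["sex"] == sex)
                & (records["age"] >= band.low)
                & (records["age"] < band.high)
            ]
            if len(sub) < 2:
                continue
            stratum = PopulationStratum(Sex(sex), AgeBand(*band))
            for comp in comps:
                out.append(
                    IntakeDistribution(
                        component=comp,
                        stratum=stratum,
                        mean=float(sub[comp].mean()),
                        sd=float(sub[comp].std(ddof=1)),
                        n=len(sub),
                        family=default_family(comp),
                    )
                )
    return out


def generate_mortality_table(spec: SyntheticMortalitySpec) -> MortalityTable:
    """Integer death counts by cause x sex x age band.

    Each (cause, sex) total is spread over age bands with exponentially
    increasing weights (doubling per ``age_doubling_decades`` decades of
    band midpoint) and largest-remainder rounding, so the spec totals are
    conserved exactly and counts rise with age.
    """
    mids = np.array([(b.low + min(b.high, 95)) / 2.0 for b in spec.age_bands])
    weights = 2.0 ** ((mids - mids[0]) / (10.0 * spec.age_doubling_decades))
    entries: dict[tuple[str, PopulationStratum], int] = {}
    for (cause, sex), total in sorted(spec.totals.items()):
        counts = apportion(int(total), weights)
        for band, count in zip(spec.age_bands, counts):
            stratum = PopulationStratum(Sex(sex), AgeBand(*band))
            entries[(cause, stratum)] = int(count)
    return MortalityTable(entries=entries, reference_year=spec.reference_year)


def default_configuration(seed: int = 0):
    """Ready-to-run Sweden-like configuration: the published intake summary
    (one 18-81 band per sex), a synthetic registry table conserving the
    published class totals, and the shipped placeholder parameter file."""
    from .domain import validate_configuration
    from .io import packaged_parameters_path, read_parameters

    band = AgeBand(18, 81)
    spec = SyntheticMortalitySpec(
        totals=default_mortality_spec(seed=seed).totals,
        age_bands=(band,),
        seed=seed,
    )
    mortality = generate_mortality_table(spec)
    rrs, meds, jss, meta = read_parameters(packaged_parameters_path())
    return validate_configuration(
        default_intake_distributions(age_band=band),
        mortality,
        rrs,
        mediations=meds,
        jshapes=jss,
        meta=meta,
    )


# --- miniature on-disk fixture -------------------------------------------

_FIXTURE_BANDS = (AgeBand(18, 50), AgeBand(50, 81))
_FIXTURE_BASE_MEANS = {
    # (component, sex) -> mean; young band a bit lower for fruits, higher salt
    ("fruits", "male"): 110.0,
    ("fruits", "female"): 150.0,
    ("fiber", "male"): 21.0,
    ("fiber", "female"): 19.0,
    ("salt", "male"): 8.8,
    ("salt", "female"): 6.8,
}


def make_test_fixture(seed: int, outdir: str | Path) -> tuple[Path, Path, Path]:
    """Write a self-consistent miniature configuration to ``outdir``.

    Two age bands, three components (fruits, fiber, salt), two causes
    (coronary heart disease, stroke); placeholder risk parameters
    consistent with each component's benefit direction. Returns paths
    (intake CSV, mortality CSV, parameter JSON). Different seeds perturb
    the intake summaries; the schema is identical.
    """
    from .io import write_intake_csv, write_mortality_csv, write_parameters

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    dists = []
    for (comp, sex), base in sorted(_FIXTURE_BASE_MEANS.items()):
        for i, band in enumerate(_FIXTURE_BANDS):
            mean = base * (1.0 + 0.06 * i) * float(rng.uniform(0.95, 1.05))
            sd = 0.35 * mean
            stratum = PopulationStratum(Sex(sex), band)
            dists.append(
                IntakeDistribution(
                    component=comp,
                    stratum=stratum,
                    mean=mean,
                    sd=sd,
                    n=80,
                    family=default_family(comp),
                )
            )

    mort_spec = SyntheticMortalitySpec(
        totals={
            ("chd", "male"): 1200,
            ("chd", "female"): 900,
            ("stroke", "male"): 400,
            ("stroke", "female"): 420,
        },
        age_bands=_FIXTURE_BANDS,
        seed=seed,
    )
    mortality = generate_mortality_table(mort_spec)

    params = {
        "meta": {
            "schema_version": 1,
            "provenance": "placeholder",
            "description": "miniature synthetic fixture parameters",
        },
        "relative_risks": [
            {
                "exposure": "fruits",
                "cause": "chd",
                "rr_per_increment": 0.93,
                "increment": 100.0,
                "reference_level": 0.0,
                "cap_level": 400.0,
                "ln_rr_se": 0.03,
                "provenance": "placeholder",
            },
            {
                "exposure": "fruits",
                "cause": "stroke",
                "rr_per_increment": 0.90,
                "increment": 100.0,
                "reference_level": 0.0,
                "cap_level": 400.0,
                "ln_rr_se": 0.04,
                "provenance": "placeholder",
            },
            {
                "exposure": "fiber",
                "cause": "chd",
                "rr_per_increment": 0.91,
                "increment": 10.0,
                "reference_level": 0.0,
                "cap_level": 35.0,
                "ln_rr_se": 0.03,
                "provenance": "placeholder",
            },
            {
                "exposure": "systolic_bp",
                "cause": "chd",
                "rr_per_increment": 1.25,
                "increment": 10.0,
                "reference_level": 0.0,
                "cap_level": None,
                "ln_rr_se": 0.04,
                "provenance": "placeholder",
            },
            {
                "exposure": "systolic_bp",
                "cause": "stroke",
                "rr_per_increment": 1.35,
                "increment": 10.0,
                "reference_level": 0.0,
                "cap_level": None,
                "ln_rr_se": 0.05,
                "provenance": "placeholder",
            },
        ],
        "mediation": [
            {
                "source": "salt",
                "mediator": "systolic_bp",
                "slope": 1.0,
                "slope_se": 0.2,
                "provenance": "placeholder",
            }
        ],
        "jshape": [],
    }

    intake_path = outdir / "intake.csv"
    mortality_path = outdir / "mortality.csv"
    params_path = outdir / "parameters.json"
    write_intake_csv(dists, intake_path)
    write_mortality_csv(mortality, mortality_path)
    write_parameters(params, params_path)
    return intake_path, mortality_path, params_path
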