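"""Typed data model shared by all pipeline stages.

The model describes a population stratified by sex and age band. Each
stratum carries, per dietary component, a parametric summary of the intake
distribution (mean, SD and a family chosen to respect the component's
support), and, per cause of death, a registry-style death count. Risk
parameters link exposures to causes either directly (log-linear relative
risk per increment of intake) or through an intermediate biological risk
factor (systolic blood pressure, serum total cholesterol, or body-mass
index, the last with a J-shaped risk curve).
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Optional

from scipy import stats

from .errors import (
    ChainingError,
    ConfigurationError,
    DuplicateParameterError,
    UnitError,
)

__all__ = [
    "Sex",
    "Unit",
    "BenefitDirection",
    "DistributionFamily",
    "DiseaseClass",
    "Mediator",
    "MEDIATOR_UNITS",
    "DietaryComponent",
    "COMPONENTS",
    "AgeBand",
    "PopulationStratum",
    "CauseOfDeath",
    "CAUSES",
    "MortalityTable",
    "IntakeDistribution",
    "gamma_params",
    "lognormal_params",
    "RelativeRiskParameter",
    "MediationParameter",
    "JShapeParameter",
    "ModelConfiguration",
    "validate_configuration",
    "default_family",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Unit(str, enum.Enum):
    G_PER_DAY = "g/day"
    PCT_ENERGY = "%E"
    MG_PER_DAY = "mg/day"
    KJ_PER_DAY = "kJ/day"


class BenefitDirection(str, enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"


class DistributionFamily(str, enum.Enum):
    NORMAL = "normal"
    LOGNORMAL = "lognormal"
    GAMMA = "gamma"


class DiseaseClass(str, enum.Enum):
    CVD = "cvd"
    CANCER = "cancer"


class Mediator(str, enum.Enum):
    SYSTOLIC_BP = "systolic_bp"
    SERUM_CHOLESTEROL = "serum_cholesterol"
    BMI = "bmi"


#: Fixed physical unit of each intermediate risk factor.
MEDIATOR_UNITS: Mapping[Mediator, str] = {
    Mediator.SYSTOLIC_BP: "mmHg",
    Mediator.SERUM_CHOLESTEROL: "mmol/L",
    Mediator.BMI: "kg/m^2",
}


@dataclass(frozen=True)
class DietaryComponent:
    """One dietary exposure with its unit, benefit direction and target.

    ``recommended_target`` is the national recommendation the counterfactual
    scenario shifts the population mean to, expressed in ``unit``.
    """

    id: str
    unit: Unit
    benefit_direction: BenefitDirection
    recommended_target: float

    def __post_init__(self) -> None:
        if self.recommended_target <= 0:
            raise ConfigurationError(
                f"recommended_target must be > 0 for {self.id!r}"
            )


def _c(cid, unit, direction, target) -> DietaryComponent:
    return DietaryComponent(cid, unit, direction, target)


#: Component registry. Targets follow the 2012 Nordic nutrient
#: recommendations as used for Sweden: the combined 500 g/day fruit-and-
#: vegetable guideline is split 250/250 between the two components, and
#: fatty-acid ranges are collapsed to single values. The energy target is a
#: reference average intake for adults; energy carries no survey row in the
#: default configuration and only matters for the BMI pathway.
COMPONENTS: Mapping[str, DietaryComponent] = {
    c.id: c
    for c in [
        _c("fruits", Unit.G_PER_DAY, BenefitDirection.INCREASE, 250.0),
        _c("vegetables", Unit.G_PER_DAY, BenefitDirection.INCREASE, 250.0),
        _c("fiber", Unit.G_PER_DAY, BenefitDirection.INCREASE, 30.0),
        _c("salt", Unit.G_PER_DAY, BenefitDirection.DECREASE, 6.0),
        _c("total_fat", Unit.PCT_ENERGY, BenefitDirection.INCREASE, 40.0),
        _c("saturated_fat", Unit.PCT_ENERGY, BenefitDirection.DECREASE, 9.0),
        _c("mufa", Unit.PCT_ENERGY, BenefitDirection.INCREASE, 20.0),
        _c("pufa", Unit.PCT_ENERGY, BenefitDirection.INCREASE, 10.0),
        _c("cholesterol", Unit.MG_PER_DAY, BenefitDirection.DECREASE, 300.0),
        _c("energy", Unit.KJ_PER_DAY, BenefitDirection.DECREASE, 8800.0),
    ]
}

#: Fat-composition components that act on serum cholesterol.
FAT_COMPONENTS = frozenset(
    {"total_fat", "saturated_fat", "mufa", "pufa", "cholesterol"}
)


def default_family(component_id: str) -> DistributionFamily:
    """Default distribution family for a component.

    Quantity components (g/day, mg/day, kJ/day) default to gamma, which
    guarantees strictly positive support; %E components default to normal.
    """
    unit = COMPONENTS[component_id].unit
    if unit is Unit.PCT_ENERGY:
        return DistributionFamily.NORMAL
    return DistributionFamily.GAMMA


class AgeBand(NamedTuple):
    """Half-open age interval in years: ``low`` inclusive, ``high`` exclusive."""

    low: int
    high: int

    def validate(self) -> "AgeBand":
        if self.low < 18:
            raise ConfigurationError(
                f"age band lower bound must be >= 18, got {self.low}"
            )
        if self.high <= self.low:
            raise ConfigurationError(f"empty age band {self.low}-{self.high}")
        return self

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.low}-{self.high}"


#: Default decade-ish banding for stratified runs; the last band is open-ended.
DEFAULT_AGE_BANDS: tuple[AgeBand, ...] = tuple(
    AgeBand(lo, hi)
    for lo, hi in [(18, 25), (25, 35), (35, 45), (45, 55), (55, 65), (65, 75), (75, 121)]
)


@dataclass(frozen=True)
class PopulationStratum:
    """A sex x age-band population cell.

    ``population_count`` is carried for reporting but excluded from
    equality/hashing so intake and mortality tables key on (sex, age band)
    alone.
    """

    sex: Sex
    age_band: AgeBand
    population_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        AgeBand(*self.age_band).validate()
        if self.population_count < 0:
            raise ConfigurationError("population_count must be >= 0")

    @property
    def key(self) -> tuple[Sex, AgeBand]:
        return (self.sex, AgeBand(*self.age_band))


_ICD_RANGE = re.compile(r"^[A-Z]\d{2}(?:-[A-Z]?\d{2})?$")


@dataclass(frozen=True)
class CauseOfDeath:
    id: str
    icd10_codes: tuple[str, ...]
    disease_class: DiseaseClass

    def __post_init__(self) -> None:
        for code in self.icd10_codes:
            if not _ICD_RANGE.match(code):
                raise ConfigurationError(f"malformed ICD-10 range {code!r}")


CAUSES: Mapping[str, CauseOfDeath] = {
    c.id: c
    for c in [
        CauseOfDeath("chd", ("I20-I25",), DiseaseClass.CVD),
        CauseOfDeath("stroke", ("I60-I69",), DiseaseClass.CVD),
        CauseOfDeath("heart_failure", ("I50",), DiseaseClass.CVD),
        CauseOfDeath("aortic_aneurysm", ("I71",), DiseaseClass.CVD),
        CauseOfDeath("pulmonary_embolism", ("I26",), DiseaseClass.CVD),
        CauseOfDeath("rheumatic_heart", ("I00-I09",), DiseaseClass.CVD),
        CauseOfDeath("hypertensive", ("I10-I15",), DiseaseClass.CVD),
        CauseOfDeath("colorectal_cancer", ("C18-C20",), DiseaseClass.CANCER),
        CauseOfDeath("lung_cancer", ("C33-C34",), DiseaseClass.CANCER),
    ]
}


@dataclass
class MortalityTable:
    """Registry-style death counts keyed by (cause id, stratum)."""

    entries: dict[tuple[str, PopulationStratum], int]
    reference_year: int = 2016

    def __post_init__(self) -> None:
        for (cause, stratum), deaths in self.entries.items():
            if cause not in CAUSES:
                raise ConfigurationError(f"unknown cause of death {cause!r}")
            if deaths < 0:
                raise ConfigurationError(
                    f"negative death count for ({cause}, {stratum})"
                )

    def strata(self) -> list[PopulationStratum]:
        seen: dict[tuple, PopulationStratum] = {}
        for (_, stratum) in self.entries:
            seen.setdefault(stratum.key, stratum)
        return list(seen.values())

    def causes(self) -> list[str]:
        return sorted({cause for (cause, _) in self.entries})

    def deaths(self, cause: str, stratum: PopulationStratum) -> int:
        return self.entries.get((cause, stratum), 0)

    def total(
        self,
        disease_class: Optional[DiseaseClass] = None,
        sex: Optional[Sex] = None,
        cause: Optional[str] = None,
    ) -> int:
        tot = 0
        for (cid, stratum), deaths in self.entries.items():
            if cause is not None and cid != cause:
                continue
            if disease_class is not None and CAUSES[cid].disease_class != disease_class:
                continue
            if sex is not None and stratum.sex != sex:
                continue
            tot += deaths
        return tot


def gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment inversion for the gamma family: (shape k, scale theta).

    k * theta == mean and k * theta**2 == sd**2 exactly.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma family requires mean > 0 and sd > 0")
    k = (mean / sd) ** 2
    theta = sd**2 / mean
    return k, theta


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment inversion for the lognormal family: (mu, sigma) on the log scale."""
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal family requires mean > 0 and sd > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class IntakeDistribution:
    """Parametric summary of one component's intake in one stratum.

    The two stored moments (mean, sd) fully determine the distribution
    within its family; family parameters are re-solved from the moments on
    demand, so shifting the mean while preserving the SD is a field
    replacement, not a sample translation.
    """

    component: str
    stratum: PopulationStratum
    mean: float
    sd: float
    n: int
    family: DistributionFamily = DistributionFamily.GAMMA

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ConfigurationError(f"unknown component {self.component!r}")
        if self.mean <= 0:
            raise ConfigurationError(
                f"mean must be > 0 for {self.component} ({self.stratum.sex.value})"
            )
        if self.sd <= 0:
            raise ConfigurationError(
                f"sd must be > 0 for {self.component} ({self.stratum.sex.value})"
            )
        if self.n <= 0:
            raise ConfigurationError("sample size n must be positive")

    @property
    def se(self) -> float:
        """Standard error of the mean: sd / sqrt(n)."""
        return self.sd / math.sqrt(self.n)

    def with_mean(self, new_mean: float) -> "IntakeDistribution":
        """Same family and SD, new mean (counterfactual shift)."""
        return replace(self, mean=new_mean)

    def frozen(self):
        """scipy frozen distribution matching (mean, sd) in this family."""
        if self.family is DistributionFamily.NORMAL:
            return stats.norm(loc=self.mean, scale=self.sd)
        if self.family is DistributionFamily.LOGNORMAL:
            mu, sigma = lognormal_params(self.mean, self.sd)
            return stats.lognorm(s=sigma, scale=math.exp(mu))
        k, theta = gamma_params(self.mean, self.sd)
        return stats.gamma(a=k, scale=theta)


@dataclass(frozen=True)
class RelativeRiskParameter:
    """Log-linear dose-response: RR multiplies by ``rr_per_increment`` for
    every ``increment`` of exposure above ``reference_level``.

    ``cap_level`` is the upper exposure threshold beyond which no further
    change in risk accrues (intake is clamped before the RR is evaluated).
    ``ln_rr_se`` is the standard error of ln RR used by the Monte Carlo
    engine. ``increment`` may be negative to express "RR per decrement"
    parameterisations; it must be nonzero.
    """

    exposure: str
    cause: str
    rr_per_increment: float
    increment: float
    reference_level: float = 0.0
    cap_level: Optional[float] = None
    ln_rr_se: float = 0.0
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.rr_per_increment <= 0:
            raise ConfigurationError("rr_per_increment must be > 0")
        if self.increment == 0:
            raise ConfigurationError(
                f"increment must be nonzero for ({self.exposure}, {self.cause})"
            )
        if self.ln_rr_se < 0:
            raise ConfigurationError("ln_rr_se must be >= 0")
        if self.cause not in CAUSES:
            raise ConfigurationError(f"unknown cause {self.cause!r}")

    @property
    def beta(self) -> float:
        """Slope of ln RR per unit of exposure."""
        return math.log(self.rr_per_increment) / self.increment


@dataclass(frozen=True)
class MediationParameter:
    """Linear link from a dietary exposure to an intermediate risk factor."""

    source: str
    mediator: Mediator
    slope: float
    slope_se: float = 0.0
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.source not in COMPONENTS:
            raise ConfigurationError(f"unknown exposure {self.source!r}")
        if self.slope_se < 0:
            raise ConfigurationError("slope_se must be >= 0")
        med = Mediator(self.mediator)
        if self.source == "energy" and med is not Mediator.BMI:
            raise ChainingError("energy acts only through BMI")
        if self.source == "salt" and med is not Mediator.SYSTOLIC_BP:
            raise ChainingError("salt acts only through systolic blood pressure")
        if self.source in FAT_COMPONENTS and med is not Mediator.SERUM_CHOLESTEROL:
            raise ChainingError(
                f"{self.source} acts only through serum cholesterol"
            )


@dataclass(frozen=True)
class JShapeParameter:
    """J-shaped (log-quadratic) BMI-mortality curve with a nadir at which
    RR equals 1 and side-specific curvatures, in ln RR per (kg/m^2)^2."""

    cause: str
    nadir: float
    curvature_below: float
    curvature_above: float

    def __post_init__(self) -> None:
        if self.cause not in CAUSES:
            raise ConfigurationError(f"unknown cause {self.cause!r}")
        if self.nadir <= 0:
            raise ConfigurationError("nadir must be > 0")
        if self.curvature_below <= 0 or self.curvature_above <= 0:
            raise ConfigurationError("curvatures must be > 0")


@dataclass(frozen=True)
class ModelConfiguration:
    """Frozen, validated bundle of everything a simulation run needs."""

    intakes: Mapping[tuple[str, PopulationStratum], IntakeDistribution]
    mortality: MortalityTable
    relative_risks: Mapping[tuple[str, str], RelativeRiskParameter]
    mediations: Mapping[tuple[str, Mediator], MediationParameter]
    jshapes: Mapping[str, JShapeParameter]
    baseline_bmi: Optional[Mapping[PopulationStratum, float]] = None
    meta: Mapping[str, object] = field(default_factory=dict)

    @property
    def components(self) -> list[str]:
        return sorted({c for (c, _) in self.intakes})

    @property
    def strata(self) -> list[PopulationStratum]:
        seen: dict[tuple, PopulationStratum] = {}
        for (_, stratum) in self.intakes:
            seen.setdefault(stratum.key, stratum)
        return sorted(seen.values(), key=lambda s: (s.sex.value, s.age_band))

    @property
    def provenance(self) -> str:
        """"placeholder" when any shipped parameter is a placeholder.

        Results computed from placeholder relative risks must never be
        presented as reproducing published estimates; the reporting layer
        checks this tag.
        """
        records = list(self.relative_risks.values()) + list(self.mediations.values())
        if any(p.provenance == "placeholder" for p in records):
            return "placeholder"
        return str(self.meta.get("provenance", "unspecified"))

    def intake(self, component: str, stratum: PopulationStratum) -> IntakeDistribution:
        return self.intakes[(component, stratum)]


def validate_configuration(
    intakes: Iterable[IntakeDistribution],
    mortality: MortalityTable,
    relative_risks: Iterable[RelativeRiskParameter],
    mediations: Iterable[MediationParameter] = (),
    jshapes: Iterable[JShapeParameter] = (),
    baseline_bmi: Optional[float | Mapping[PopulationStratum, float]] = None,
    meta: Optional[Mapping[str, object]] = None,
) -> ModelConfiguration:
    """Cross-check all inputs and return a frozen :class:`ModelConfiguration`.

    Raises
    ------
    ConfigurationError
        When the (component x stratum) intake grid has holes, a mortality
        stratum lacks intake coverage, or an active BMI pathway has no
        baseline BMI.
    DuplicateParameterError
        When two parameter records cover the same key.
    """
    intake_map: dict[tuple[str, PopulationStratum], IntakeDistribution] = {}
    for dist in intakes:
        key = (dist.component, dist.stratum)
        if key in intake_map:
            raise DuplicateParameterError(
                f"duplicate intake row for ({dist.component}, "
                f"{dist.stratum.sex.value}, {dist.stratum.age_band})"
            )
        intake_map[key] = dist

    strata = {}
    for (_, stratum) in intake_map:
        strata.setdefault(stratum.key, stratum)
    components = sorted({c for (c, _) in intake_map})

    # The intake grid must be complete: every component in every stratum.
    for comp in components:
        for stratum in strata.values():
            if (comp, stratum) not in intake_map:
                raise ConfigurationError(
                    f"missing intake row for ({comp}, {stratum.sex.value}, "
                    f"age {stratum.age_band[0]}-{stratum.age_band[1]})"
                )

    # Age bands within each sex must be disjoint.
    for sex in Sex:
        bands = sorted(
            {s.age_band for s in strata.values() if s.sex is sex}
        )
        for (a, b) in zip(bands, bands[1:]):
            if b[0] < a[1]:
                raise ConfigurationError(
                    f"overlapping age bands {a} and {b} for {sex.value}"
                )

    # Every mortality stratum needs intake coverage.
    for stratum in mortality.strata():
        if stratum.key not in strata:
            raise ConfigurationError(
                f"mortality stratum ({stratum.sex.value}, age "
                f"{stratum.age_band[0]}-{stratum.age_band[1]}) has no intake data"
            )

    rr_map: dict[tuple[str, str], RelativeRiskParameter] = {}
    for p in relative_risks:
        key = (p.exposure, p.cause)
        if key in rr_map:
            raise DuplicateParameterError(f"duplicate relative risk for {key}")
        valid_exposures = set(COMPONENTS) | {m.value for m in Mediator}
        if p.exposure not in valid_exposures:
            raise ConfigurationError(f"unknown exposure {p.exposure!r}")
        rr_map[key] = p

    med_map: dict[tuple[str, Mediator], MediationParameter] = {}
    for m in mediations:
        key = (m.source, Mediator(m.mediator))
        if key in med_map:
            raise DuplicateParameterError(f"duplicate mediation for {key}")
        med_map[key] = m

    js_map: dict[str, JShapeParameter] = {}
    for j in jshapes:
        if j.cause in js_map:
            raise DuplicateParameterError(f"duplicate J-shape for {j.cause}")
        js_map[j.cause] = j

    bmi_map: Optional[dict[PopulationStratum, float]] = None
    if baseline_bmi is not None:
        if isinstance(baseline_bmi, Mapping):
            bmi_map = dict(baseline_bmi)
        else:
            bmi_map = {s: float(baseline_bmi) for s in strata.values()}

    # An active BMI pathway (energy intake + energy->bmi link + a J-shape or
    # bmi-scale RR) needs a baseline BMI level to evaluate the curve at.
    bmi_active = (
        "energy" in components
        and ("energy", Mediator.BMI) in med_map
        and (js_map or any(exp == Mediator.BMI.value for (exp, _) in rr_map))
    )
    if bmi_active and not bmi_map:
        raise ConfigurationError(
            "BMI pathway is active but no baseline BMI was provided"
        )

    return ModelConfiguration(
        intakes=intake_map,
        mortality=mortality,
        relative_risks=rr_map,
        mediations=med_map,
        jshapes=js_map,
        baseline_bmi=bmi_map,
        meta=dict(meta or {}),
    )
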