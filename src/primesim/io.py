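"""Readers and writers for the file dialects, plus run configuration.

All CSV dialects are comma-separated, decimal-point, UTF-8 with LF line
endings regardless of locale (the source tables are Swedish; locale-aware
parsing is deliberately disabled by using the csv module directly).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .domain import (
    CAUSES,
    COMPONENTS,
    AgeBand,
    IntakeDistribution,
    JShapeParameter,
    MediationParameter,
    ModelConfiguration,
    MortalityTable,
    PopulationStratum,
    RelativeRiskParameter,
    Sex,
    Unit,
    default_family,
    validate_configuration,
)
from .errors import ConfigurationError, ParseError, UnitError
from .simulate import ScenarioResult

__all__ = [
    "INTAKE_HEADER",
    "MORTALITY_HEADER",
    "RESULTS_HEADER",
    "read_intake_csv",
    "write_intake_csv",
    "read_mortality_csv",
    "write_mortality_csv",
    "read_parameters",
    "write_parameters",
    "parse_parameters",
    "packaged_parameters_path",
    "load_configuration",
    "RunConfig",
    "load_run_config",
    "write_results_csv",
    "read_results_csv",
    "write_point_csv",
    "render_markdown_report",
]

INTAKE_HEADER = ["component", "sex", "age_low", "age_high", "mean", "se", "n", "unit"]
MORTALITY_HEADER = ["cause", "icd10", "sex", "age_low", "age_high", "deaths"]
RESULTS_HEADER = ["scenario", "cause", "sex", "mean", "lower", "upper", "n_iter", "seed"]


def _float(raw: str, line: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"line {line}: non-numeric {column} {raw!r}") from None


def read_intake_csv(path: str | Path) -> list[IntakeDistribution]:
    """Parse an intake summary table into distributions (sd = se * sqrt(n)).

    Malformed rows raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    dists = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != INTAKE_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(INTAKE_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            comp = row["component"]
            if comp not in COMPONENTS:
                raise ParseError(f"line {i}: unknown component {comp!r}")
            if row["unit"] != COMPONENTS[comp].unit.value:
                raise UnitError(
                    f"line {i}: unit {row['unit']!r} does not match "
                    f"{COMPONENTS[comp].unit.value!r} for {comp}"
                )
            try:
                sex = Sex(row["sex"])
            except ValueError:
                raise ParseError(f"line {i}: unknown sex {row['sex']!r}") from None
            mean = _float(row["mean"], i, "mean")
            se = _float(row["se"], i, "se")
            try:
                n = int(row["n"])
                age_low = int(row["age_low"])
                age_high = int(row["age_high"])
            except ValueError:
                raise ParseError(f"line {i}: non-integer n/age bound") from None
            if n <= 0:
                raise ParseError(f"line {i}: sample size n must be positive")
            if se <= 0:
                raise ParseError(f"line {i}: se must be positive")
            stratum = PopulationStratum(sex, AgeBand(age_low, age_high))
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


def write_intake_csv(dists: Iterable[IntakeDistribution], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(INTAKE_HEADER)
        for d in sorted(
            dists, key=lambda d: (d.component, d.stratum.sex.value, d.stratum.age_band)
        ):
            writer.writerow(
                [
                    d.component,
                    d.stratum.sex.value,
                    d.stratum.age_band[0],
                    d.stratum.age_band[1],
                    repr(d.mean),
                    repr(d.se),
                    d.n,
                    COMPONENTS[d.component].unit.value,
                ]
            )


def read_mortality_csv(path: str | Path, reference_year: int = 2016) -> MortalityTable:
    path = Path(path)
    entries: dict[tuple[str, PopulationStratum], int] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != MORTALITY_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(MORTALITY_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            cause = row["cause"]
            if cause not in CAUSES:
                raise ParseError(f"line {i}: unknown cause {cause!r}")
            try:
                sex = Sex(row["sex"])
            except ValueError:
                raise ParseError(f"line {i}: unknown sex {row['sex']!r}") from None
            try:
                deaths = int(row["deaths"])
                age_low = int(row["age_low"])
                age_high = int(row["age_high"])
            except ValueError:
                raise ParseError(f"line {i}: non-integer deaths/age bound") from None
            if deaths < 0:
                raise ParseError(f"line {i}: negative death count")
            stratum = PopulationStratum(sex, AgeBand(age_low, age_high))
            key = (cause, stratum)
            if key in entries:
                raise ParseError(f"line {i}: duplicate row for {cause}/{sex.value}")
            entries[key] = deaths
    return MortalityTable(entries=entries, reference_year=reference_year)


def write_mortality_csv(table: MortalityTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(MORTALITY_HEADER)
        for (cause, stratum), deaths in sorted(
            table.entries.items(),
            key=lambda kv: (kv[0][0], kv[0][1].sex.value, kv[0][1].age_band),
        ):
            writer.writerow(
                [
                    cause,
                    ";".join(CAUSES[cause].icd10_codes),
                    stratum.sex.value,
                    stratum.age_band[0],
                    stratum.age_band[1],
                    deaths,
                ]
            )


def parse_parameters(
    payload: Mapping,
) -> tuple[
    list[RelativeRiskParameter],
    list[MediationParameter],
    list[JShapeParameter],
    dict,
]:
    """Validate the JSON schema and build typed parameter records."""
    for key in ("relative_risks", "mediation", "jshape", "meta"):
        if key not in payload:
            raise ParseError(f"parameter file missing top-level key {key!r}")
    meta = dict(payload["meta"])
    default_prov = str(meta.get("provenance", "unspecified"))
    rrs = [
        RelativeRiskParameter(
            exposure=rec["exposure"],
            cause=rec["cause"],
            rr_per_increment=float(rec["rr_per_increment"]),
            increment=float(rec["increment"]),
            reference_level=float(rec.get("reference_level", 0.0)),
            cap_level=(
                None if rec.get("cap_level") is None else float(rec["cap_level"])
            ),
            ln_rr_se=float(rec.get("ln_rr_se", 0.0)),
            provenance=str(rec.get("provenance", default_prov)),
        )
        for rec in payload["relative_risks"]
    ]
    meds = [
        MediationParameter(
            source=rec["source"],
            mediator=rec["mediator"],
            slope=float(rec["slope"]),
            slope_se=float(rec.get("slope_se", 0.0)),
            provenance=str(rec.get("provenance", default_prov)),
        )
        for rec in payload["mediation"]
    ]
    jss = [
        JShapeParameter(
            cause=rec["cause"],
            nadir=float(rec["nadir"]),
            curvature_below=float(rec["curvature_below"]),
            curvature_above=float(rec["curvature_above"]),
        )
        for rec in payload["jshape"]
    ]
    return rrs, meds, jss, meta


def read_parameters(path: str | Path):
    with open(path, encoding="utf-8") as handle:
        try:
            payload = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from None
    return parse_parameters(payload)


def write_parameters(payload: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")


def packaged_parameters_path() -> Path:
    """Path to the shipped placeholder dose-response parameter file."""
    return Path(resources.files("primesim") / "data" / "parameters_placeholder.json")


def load_configuration(
    intake_path: str | Path,
    mortality_path: str | Path,
    parameters_path: str | Path,
    baseline_bmi: Optional[float] = None,
) -> ModelConfiguration:
    """Read the three input files and return a validated configuration."""
    for p in (intake_path, mortality_path, parameters_path):
        if not Path(p).exists():
            raise ConfigurationError(f"input file does not exist: {p}")
    intakes = read_intake_csv(intake_path)
    mortality = read_mortality_csv(mortality_path)
    rrs, meds, jss, meta = read_parameters(parameters_path)
    return validate_configuration(
        intakes,
        mortality,
        rrs,
        mediations=meds,
        jshapes=jss,
        baseline_bmi=baseline_bmi,
        meta=meta,
    )


@dataclass
class RunConfig:
    """Run configuration (YAML or JSON on disk)."""

    intake_path: Path
    mortality_path: Path
    parameters_path: Path
    output_dir: Path = Path("results")
    grouping: Optional[dict[str, list[str]]] = None
    n_iter: int = 5000
    seed: int = 0
    baseline_bmi: Optional[float] = None
    markdown_report: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 2:
            raise ConfigurationError("n_iter must be >= 2 for Monte Carlo mode")
        for p in (self.intake_path, self.mortality_path, self.parameters_path):
            if not Path(p).exists():
                raise ConfigurationError(f"input file does not exist: {p}")


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        payload = yaml.safe_load(handle)  # YAML is a JSON superset
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: run config must be a mapping")
    base = path.parent
    def _p(key):
        return (base / payload[key]).resolve() if key in payload else None
    try:
        return RunConfig(
            intake_path=_p("intake_path"),
            mortality_path=_p("mortality_path"),
            parameters_path=_p("parameters_path"),
            output_dir=Path(payload.get("output_dir", base / "results")),
            grouping=payload.get("grouping"),
            n_iter=int(payload.get("n_iter", 5000)),
            seed=int(payload.get("seed", 0)),
            baseline_bmi=payload.get("baseline_bmi"),
            markdown_report=bool(payload.get("markdown_report", True)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing run-config key {exc}") from None


def write_results_csv(result: ScenarioResult, path: str | Path) -> None:
    """Tidy Monte Carlo results. For point-only results mean=point and the
    interval collapses onto it."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(RESULTS_HEADER)
        for key in result.point:
            label, cause, sex = key
            mean = result.mean[key] if result.mean is not None else result.point[key]
            lower = result.lower[key] if result.lower is not None else mean
            upper = result.upper[key] if result.upper is not None else mean
            writer.writerow(
                [
                    label,
                    cause,
                    sex,
                    repr(float(mean)),
                    repr(float(lower)),
                    repr(float(upper)),
                    result.n_iterations,
                    "" if result.seed is None else result.seed,
                ]
            )


def read_results_csv(path: str | Path) -> ScenarioResult:
    mean: dict = {}
    lower: dict = {}
    upper: dict = {}
    n_iter = 1
    seed: Optional[int] = None
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != RESULTS_HEADER:
            raise ParseError(f"{path}: unexpected results header {reader.fieldnames}")
        for row in reader:
            key = (row["scenario"], row["cause"], row["sex"])
            mean[key] = float(row["mean"])
            lower[key] = float(row["lower"])
            upper[key] = float(row["upper"])
            n_iter = int(row["n_iter"])
            seed = int(row["seed"]) if row["seed"] else None
    return ScenarioResult(
        point=dict(mean),
        mean=mean,
        lower=lower,
        upper=upper,
        n_iterations=n_iter,
        seed=seed,
    )


def write_point_csv(result: ScenarioResult, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["scenario", "cause", "sex", "deaths_averted"])
        for (label, cause, sex), value in result.point.items():
            writer.writerow([label, cause, sex, repr(float(value))])


def _df_to_markdown(df) -> str:
    """Minimal GitHub-style table rendering (no external dependency)."""
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def render_markdown_report(result: ScenarioResult, mortality=None) -> str:
    """Human-readable rendering of the two standard tables.

    Results computed from placeholder parameters carry an explicit notice:
    they characterise the pipeline, not any published national estimate.
    """
    from .simulate import summarize

    parts = ["# Deaths prevented or delayed\n"]
    if result.provenance == "placeholder":
        parts.append(
            "> **Placeholder parameters.** The dose-response parameter file "
            "in use is a placeholder set; absolute numbers below must not be "
            "read as reproducing published estimates.\n"
        )
    if result.n_iterations > 1:
        parts.append(
            f"Central values are means over {result.n_iterations} Monte Carlo "
            "draws; intervals are 2.5th-97.5th percentiles.\n"
        )
    parts.append("## By dietary change\n")
    parts.append(_df_to_markdown(summarize(result, "component_by_sex")))
    parts.append("\n## By cause of death (combined scenario)\n")
    parts.append(
        _df_to_markdown(summarize(result, "cause_by_sex", mortality=mortality))
    )
    parts.append("")
    return "\n".join(parts)
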