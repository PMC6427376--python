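"""Baseline and counterfactual scenario construction.

A counterfactual shifts each selected component's population mean to its
recommended target while leaving the within-population SD (and the
distribution family) untouched. For the moment-parameterised families used
here that is a parameter re-solve, not a translation of samples, so gamma
margins stay strictly positive with no truncated mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .domain import (
    COMPONENTS,
    IntakeDistribution,
    ModelConfiguration,
    PopulationStratum,
)
from .errors import ConfigurationError

__all__ = [
    "Scenario",
    "BASELINE_LABEL",
    "ALL_LABEL",
    "DEFAULT_GROUPS",
    "baseline_scenario",
    "build_counterfactual",
    "default_grouping",
    "build_component_scenarios",
    "default_targets",
]

BASELINE_LABEL = "baseline"
ALL_LABEL = "All dietary guidelines combined"

#: Component groups matching the standard reporting rows.
DEFAULT_GROUPS: Mapping[str, tuple[str, ...]] = {
    "Fruits and vegetables": ("fruits", "vegetables"),
    "Fiber": ("fiber",),
    "Fats": ("total_fat", "saturated_fat", "mufa", "pufa", "cholesterol"),
    "Salt": ("salt",),
}


@dataclass(frozen=True)
class Scenario:
    """A complete intake map plus the set of components that were shifted."""

    label: str
    distributions: Mapping[tuple[str, PopulationStratum], IntakeDistribution]
    active_components: frozenset[str]

    @property
    def components(self) -> list[str]:
        return sorted({c for (c, _) in self.distributions})


def default_targets(components: Iterable[str]) -> dict[str, float]:
    """Recommended-intake targets from the component registry."""
    return {c: COMPONENTS[c].recommended_target for c in components}


def baseline_scenario(
    config: ModelConfiguration, label: str = BASELINE_LABEL
) -> Scenario:
    return Scenario(
        label=label,
        distributions=dict(config.intakes),
        active_components=frozenset(),
    )


def build_counterfactual(
    baseline: Scenario,
    targets: Mapping[str, float],
    components: Iterable[str],
    label: str = "counterfactual",
) -> Scenario:
    """Shift the selected components' means to their targets, SD preserved.

    The shift applies in both directions: a deficit component's mean rises
    to the target, an excess component's mean falls to it. Non-selected
    components are copied verbatim.
    """
    selected = set(components)
    available = {c for (c, _) in baseline.distributions}
    unknown = selected - available
    if unknown:
        raise ConfigurationError(
            f"scenario {label!r} selects components with no intake data: "
            f"{sorted(unknown)}"
        )
    for comp in selected:
        if comp not in targets:
            raise ConfigurationError(f"no recommended target for {comp!r}")
        if targets[comp] <= 0:
            raise ConfigurationError(
                f"recommended target for {comp!r} must be > 0"
            )
    new_dists = {}
    for key, dist in baseline.distributions.items():
        comp, _ = key
        if comp in selected:
            new_dists[key] = dist.with_mean(targets[comp])
        else:
            new_dists[key] = dist
    return Scenario(
        label=label,
        distributions=new_dists,
        active_components=frozenset(selected),
    )


def default_grouping(available: Iterable[str]) -> dict[str, tuple[str, ...]]:
    """Standard grouping restricted to the components actually present,
    with a combined all-components group appended."""
    available = set(available)
    grouping: dict[str, tuple[str, ...]] = {}
    grouped: list[str] = []
    for group_label, members in DEFAULT_GROUPS.items():
        present = tuple(c for c in members if c in available)
        if present:
            grouping[group_label] = present
            grouped.extend(present)
    leftovers = tuple(sorted(available - set(grouped) - {"energy"}))
    for comp in leftovers:
        grouping[comp] = (comp,)
    if grouping:
        grouping[ALL_LABEL] = tuple(
            c for members in grouping.values() for c in members
        )
    return grouping


def build_component_scenarios(
    baseline: Scenario,
    targets: Mapping[str, float],
    grouping: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[Scenario]:
    """One counterfactual per component group.

    With the default grouping this yields the standard five rows: fruits
    and vegetables, fiber, fats, salt, and all recommendations combined.
    """
    if grouping is None:
        grouping = default_grouping(c for (c, _) in baseline.distributions)
    scenarios = []
    for label, members in grouping.items():
        scenarios.append(
            build_counterfactual(baseline, targets, members, label=label)
        )
    return scenarios
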