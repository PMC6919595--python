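"""Readiness-indicator registry.

Each of the 19 maternal and newborn health interventions has a fixed
checklist of structural components (staff training, guidelines, equipment,
medicines) that a facility must have available to be counted as *ready* to
deliver it. The registry encodes those checklists, the care period each
intervention belongs to (antenatal, childbirth, postnatal), and which
components are assessed only in SPA surveys.

The registry ships with the package as a YAML configuration file; custom
registries can be loaded from any file with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

PERIODS = ("antenatal", "childbirth", "postnatal")
SURVEY_TYPES = ("SPA", "SARA")

#: care period -> expected number of interventions in the shipped registry
_PERIOD_COUNTS = {"antenatal": 8, "childbirth": 7, "postnatal": 4}


class ConfigurationError(ValueError):
    """A registry, ground truth, or run configuration is inconsistent."""


class DataError(ValueError):
    """An input record is missing or malformed."""


@dataclass(frozen=True)
class IndicatorDefinition:
    """Readiness checklist for one intervention.

    ``spa_only_components`` are dropped from the requirement set when the
    facility survey is a SARA (they are not assessed there).
    """

    intervention_id: str
    label: str
    period: str
    required_components: tuple[str, ...]
    spa_only_components: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ConfigurationError(
                f"{self.intervention_id}: unknown period {self.period!r}"
            )
        if not self.required_components:
            raise ConfigurationError(
                f"{self.intervention_id}: required_components is empty"
            )
        extra = set(self.spa_only_components) - set(self.required_components)
        if extra:
            raise ConfigurationError(
                f"{self.intervention_id}: spa_only components {sorted(extra)} "
                "not in required_components"
            )

    def applicable_components(self, survey_type: str) -> tuple[str, ...]:
        """Requirement set under a given survey type.

        SARA surveys do not assess SPA-only components, so those are
        excluded. May be empty, in which case the indicator cannot be
        constructed for that survey type.
        """
        if survey_type not in SURVEY_TYPES:
            raise ConfigurationError(f"unknown survey type {survey_type!r}")
        if survey_type == "SPA":
            return self.required_components
        spa_only = set(self.spa_only_components)
        return tuple(c for c in self.required_components if c not in spa_only)


def load_registry(path: str | Path | None = None) -> list[IndicatorDefinition]:
    """Load indicator definitions from YAML (the packaged default if no path).

    The packaged registry is validated to contain exactly 19 interventions:
    8 antenatal, 7 childbirth, 4 postnatal.
    """
    if path is None:
        ref = resources.files("careimpact.data") / "indicator_registry.yaml"
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
        validate = True
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        validate = False

    defs = []
    seen: set[str] = set()
    for item in raw["interventions"]:
        d = IndicatorDefinition(
            intervention_id=item["id"],
            label=item.get("label", item["id"]),
            period=item["period"],
            required_components=tuple(item["components"]),
            spa_only_components=tuple(item.get("spa_only", ())),
        )
        if d.intervention_id in seen:
            raise ConfigurationError(f"duplicate intervention {d.intervention_id}")
        seen.add(d.intervention_id)
        defs.append(d)

    if validate:
        counts = {p: sum(1 for d in defs if d.period == p) for p in PERIODS}
        if counts != _PERIOD_COUNTS:
            raise ConfigurationError(
                f"packaged registry has period counts {counts}, "
                f"expected {_PERIOD_COUNTS}"
            )
    return defs


def registry_components(registry: list[IndicatorDefinition]) -> list[str]:
    """All component codes referenced by a registry, in first-use order."""
    out: list[str] = []
    seen: set[str] = set()
    for d in registry:
        for c in d.required_components:
            if c not in seen:
                seen.add(c)
                out.append(c)
    return out


def by_id(registry: list[IndicatorDefinition]) -> dict[str, IndicatorDefinition]:
    return {d.intervention_id: d for d in registry}
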