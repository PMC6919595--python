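"""Link facility-readiness surveys to household utilization surveys.

Baseline *effective coverage* of an intervention is approximated as

    coverage = U x sum_s share_s x readiness_s

where ``U`` is the utilization cap for the intervention's care period (the
proportion of women with four or more antenatal visits for antenatal
interventions; the proportion of facility deliveries for childbirth and
postnatal interventions), ``share_s`` is the share of care contacts occurring
in facility stratum ``s``, and ``readiness_s`` is the weighted proportion of
facilities in stratum ``s`` that have every structural component the
intervention requires.

A facility survey and a household survey may only be linked when their
fieldwork years are at most two years apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .registry import (
    SURVEY_TYPES,
    ConfigurationError,
    DataError,
    IndicatorDefinition,
    load_registry,
)

MAX_LINK_GAP_YEARS = 2.0

#: provenance labels for a coverage estimate
PROVENANCES = ("linked", "median_proxy", "q25_proxy", "q75_proxy")


@dataclass
class FacilitySurvey:
    """Facility records with per-component availability flags.

    ``records`` holds one row per facility with columns ``facility_id``,
    ``stratum``, ``weight`` (positive survey weight) and one 0/1 column per
    component code.
    """

    records: pd.DataFrame
    survey_type: str
    survey_year: float

    def __post_init__(self) -> None:
        if self.survey_type not in SURVEY_TYPES:
            raise ConfigurationError(f"unknown survey type {self.survey_type!r}")
        for col in ("facility_id", "stratum", "weight"):
            if col not in self.records.columns:
                raise DataError(f"facility survey missing column {col!r}")
        if (self.records["weight"] <= 0).any():
            raise DataError("facility survey weights must be strictly positive")

    @property
    def component_columns(self) -> list[str]:
        skip = {"facility_id", "stratum", "weight"}
        return [c for c in self.records.columns if c not in skip]

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class UtilizationProfile:
    """Country-level care-seeking measures from a household survey."""

    country_id: str
    anc4_plus: float
    hfd: float
    stratum_shares: dict[str, float]
    survey_year: float = 2016.0

    def __post_init__(self) -> None:
        for name, v in (("anc4_plus", self.anc4_plus), ("hfd", self.hfd)):
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name}={v} outside [0, 1]")
        total = sum(self.stratum_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"stratum shares sum to {total}, expected 1")
        if any(s < 0 for s in self.stratum_shares.values()):
            raise DataError("stratum shares must be nonnegative")

    def utilization_for(self, period: str) -> float:
        """Utilization cap for a care period (ANC4+ or facility delivery)."""
        if period == "antenatal":
            return self.anc4_plus
        if period in ("childbirth", "postnatal"):
            return self.hfd
        raise ConfigurationError(f"unknown period {period!r}")


@dataclass
class SurveyPair:
    """A facility survey linked to a household survey for one country."""

    facility_survey: FacilitySurvey
    household_survey: UtilizationProfile
    facility_survey_year: float
    household_survey_year: float

    def __post_init__(self) -> None:
        for y in (self.facility_survey_year, self.household_survey_year):
            if not 2000 <= y <= 2030:
                raise DataError(f"survey year {y} outside plausible range")


@dataclass
class EffectiveCoverage:
    """Per-intervention baseline effective coverage for one country.

    Interventions whose indicator could not be constructed for the survey
    type (all required components SPA-only under SARA) are listed in
    ``absent`` rather than given a fabricated value.
    """

    country_id: str
    values: dict[str, float]
    provenance: str
    absent: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ConfigurationError(f"unknown provenance {self.provenance!r}")
        bad = {k: v for k, v in self.values.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise DataError(f"coverage values outside [0, 1]: {bad}")


# ---------------------------------------------------------------------------
# readiness evaluation


def evaluate_readiness(
    record: Mapping[str, object],
    definition: IndicatorDefinition,
    survey_type: str,
) -> bool:
    """True iff the facility has every applicable required component.

    Strict conjunction: no partial credit. SPA-only components are excluded
    from the requirement set for SARA surveys.
    """
    applicable = definition.applicable_components(survey_type)
    if not applicable:
        raise ConfigurationError(
            f"indicator {definition.intervention_id} has no assessable "
            f"components under {survey_type}"
        )
    for comp in applicable:
        val = record.get(comp) if hasattr(record, "get") else record[comp]
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise DataError(
                f"record missing component {comp!r} required by "
                f"{definition.intervention_id}"
            )
        if not bool(val):
            return False
    return True


def readiness_by_stratum(
    survey: FacilitySurvey, definition: IndicatorDefinition
) -> dict[str, float]:
    """Weighted proportion of ready facilities per stratum.

    Weights are normalized within each stratum (design-based estimation).
    Strata absent from the survey are omitted from the result.
    """
    applicable = definition.applicable_components(survey.survey_type)
    if not applicable:
        raise ConfigurationError(
            f"indicator {definition.intervention_id} has no assessable "
            f"components under {survey.survey_type}"
        )
    df = survey.records
    missing = [c for c in applicable if c not in df.columns]
    if missing:
        raise DataError(f"facility survey missing component column(s) {missing}")
    if df[list(applicable)].isna().any().any():
        bad = [c for c in applicable if df[c].isna().any()]
        raise DataError(f"missing component values in column(s) {bad}")

    ready = df[list(applicable)].astype(bool).all(axis=1)
    out: dict[str, float] = {}
    for stratum, idx in df.groupby("stratum").groups.items():
        w = df.loc[idx, "weight"].to_numpy(dtype=float)
        total = w.sum()
        if total <= 0:
            raise DataError(f"stratum {stratum!r} has zero total weight")
        out[str(stratum)] = float(w[ready.loc[idx].to_numpy()].sum() / total)
    return out


def effective_coverage(
    readiness: Mapping[str, float],
    profile: UtilizationProfile,
    period: str,
) -> float:
    """Population-level effective coverage: utilization x mean readiness.

    The mean readiness is weighted by the share of care contacts in each
    facility stratum. Strata with zero share may lack a readiness estimate;
    a nonzero-share stratum without one is an error.
    """
    util = profile.utilization_for(period)
    acc = 0.0
    for stratum, share in profile.stratum_shares.items():
        if share == 0:
            continue
        if stratum not in readiness:
            raise DataError(
                f"stratum {stratum!r} has share {share} but no readiness estimate"
            )
        acc += share * readiness[stratum]
    value = util * acc
    # guard against floating-point overshoot of the [0, 1] bound
    return float(min(max(value, 0.0), 1.0))


def validate_link(facility_year: float, household_year: float) -> bool:
    """True iff the two survey years are at most two years apart."""
    if not (np.isfinite(facility_year) and np.isfinite(household_year)):
        raise DataError("survey years must be finite")
    return abs(facility_year - household_year) <= MAX_LINK_GAP_YEARS


def estimate_country_baseline(
    pair: SurveyPair,
    registry: list[IndicatorDefinition] | None = None,
) -> EffectiveCoverage:
    """Baseline effective coverage for every constructible intervention.

    Refuses pairs whose survey years violate the two-year link rule.
    Interventions whose indicator cannot be built for the facility survey
    type are flagged absent rather than scored.
    """
    if registry is None:
        registry = load_registry()
    if not validate_link(pair.facility_survey_year, pair.household_survey_year):
        gap = abs(pair.facility_survey_year - pair.household_survey_year)
        raise DataError(
            f"survey year gap {gap:g} exceeds {MAX_LINK_GAP_YEARS:g} years; "
            "link refused"
        )
    survey = pair.facility_survey
    profile = pair.household_survey
    values: dict[str, float] = {}
    absent: list[str] = []
    for definition in registry:
        if not definition.applicable_components(survey.survey_type):
            absent.append(definition.intervention_id)
            continue
        readiness = readiness_by_stratum(survey, definition)
        values[definition.intervention_id] = effective_coverage(
            readiness, profile, definition.period
        )
    return EffectiveCoverage(
        country_id=profile.country_id,
        values=values,
        provenance="linked",
        absent=tuple(absent),
    )


# ---------------------------------------------------------------------------
# CSV round trips


def write_coverage_csv(
    coverages: list[EffectiveCoverage],
    registry: list[IndicatorDefinition],
    path: str | Path,
) -> pd.DataFrame:
    periods = {d.intervention_id: d.period for d in registry}
    rows = []
    for cov in coverages:
        for iid, value in sorted(cov.values.items()):
            rows.append(
                {
                    "country_id": cov.country_id,
                    "intervention_id": iid,
                    "period": periods[iid],
                    "coverage": value,
                    "provenance": cov.provenance,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_facility_csv(
    path: str | Path, survey_type: str, survey_year: float
) -> FacilitySurvey:
    df = pd.read_csv(path)
    return FacilitySurvey(records=df, survey_type=survey_type, survey_year=survey_year)


def read_utilization_csv(path: str | Path) -> list[UtilizationProfile]:
    """Read long-format utilization CSV (one row per country x stratum)."""
    df = pd.read_csv(path)
    profiles = []
    for country, grp in df.groupby("country_id", sort=False):
        shares = dict(zip(grp["stratum"], grp["stratum_share"].astype(float)))
        profiles.append(
            UtilizationProfile(
                country_id=str(country),
                anc4_plus=float(grp["anc4_plus"].iloc[0]),
                hfd=float(grp["hfd"].iloc[0]),
                stratum_shares=shares,
                survey_year=float(grp["survey_year"].iloc[0])
                if "survey_year" in grp
                else 2016.0,
            )
        )
    return profiles
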