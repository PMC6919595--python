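"""Deterministic cause-specific lives-saved engine.

Each intervention reduces deaths from specific causes with a given efficacy
acting on a given affected fraction of that cause's deaths. Interventions
acting on the same cause combine multiplicatively through a residual
mortality factor

    R(c) = prod_i (1 - efficacy_i x affected_fraction_i x coverage_i)

which structurally precludes double counting: the joint reduction from
several interventions is never more than the sum of their individual
reductions. The observed baseline death envelope is taken to already
reflect baseline coverage, so deaths under a coverage vector ``c(y)`` are
scaled by the residual *ratio*

    deaths(y) = deaths(2016) x R(c(y)) / R(c(2016)).

Lives saved is the difference between the counterfactual (coverage frozen
at baseline) and the scale-up scenario. Birth and death envelopes are held
constant over the projection window; no demographic projection is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .registry import ConfigurationError, DataError

OUTCOMES = ("maternal", "neonatal", "stillbirth")

MATERNAL_CAUSES = (
    "hemorrhage",
    "hypertensive_disorders",
    "sepsis",
    "obstructed_labor",
    "other_maternal",
)
NEONATAL_CAUSES = (
    "prematurity",
    "intrapartum_related",
    "sepsis",
    "pneumonia",
    "tetanus",
    "other_neonatal",
)
STILLBIRTH_CAUSES = ("antepartum", "intrapartum")

CAUSES = {
    "maternal": MATERNAL_CAUSES,
    "neonatal": NEONATAL_CAUSES,
    "stillbirth": STILLBIRTH_CAUSES,
}

#: relative tolerance for conservation checks
CONSERVATION_RTOL = 1e-9


@dataclass
class EpiProfile:
    """Births and cause-specific death envelope for one country-year."""

    country_id: str
    year: int
    live_births: float
    total_births: float
    deaths: dict[tuple[str, str], float]  # (outcome, cause) -> deaths

    def __post_init__(self) -> None:
        if self.total_births < self.live_births:
            raise DataError("total_births must be >= live_births")
        if self.live_births < 0:
            raise DataError("live_births must be nonnegative")
        bad = {k: v for k, v in self.deaths.items() if v < 0}
        if bad:
            raise DataError(f"negative death counts: {bad}")

    def outcome_total(self, outcome: str) -> float:
        return sum(v for (o, _), v in self.deaths.items() if o == outcome)


@dataclass(frozen=True)
class EfficacyEntry:
    """One intervention's effect on one (outcome, cause) pair."""

    intervention_id: str
    outcome: str
    cause: str
    efficacy: float
    affected_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficacy <= 1.0:
            raise ConfigurationError(f"efficacy {self.efficacy} outside [0, 1]")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ConfigurationError(
                f"affected_fraction {self.affected_fraction} outside [0, 1]"
            )

    @property
    def effect_size(self) -> float:
        return self.efficacy * self.affected_fraction


def load_efficacy(path: str | Path | None = None) -> list[EfficacyEntry]:
    """Load the efficacy matrix (the packaged illustrative default if no path).

    The packaged matrix respects the intervention -> outcome/cause topology
    of the maternal/newborn impact pathways but its numbers are illustrative
    configuration values, not authoritative effectiveness estimates.
    """
    if path is None:
        ref = resources.files("careimpact.data") / "efficacy_default.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    entries = []
    seen: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.intervention_id, row.outcome, row.cause)
        if key in seen:
            raise ConfigurationError(f"duplicate efficacy entry {key}")
        seen.add(key)
        if row.outcome not in OUTCOMES:
            raise ConfigurationError(f"unknown outcome {row.outcome!r}")
        entries.append(
            EfficacyEntry(
                intervention_id=str(row.intervention_id),
                outcome=str(row.outcome),
                cause=str(row.cause),
                efficacy=float(row.efficacy),
                affected_fraction=float(row.affected_fraction),
            )
        )
    return entries


def entries_by_cause(
    config: Iterable[EfficacyEntry],
) -> dict[tuple[str, str], list[EfficacyEntry]]:
    out: dict[tuple[str, str], list[EfficacyEntry]] = {}
    for e in config:
        out.setdefault((e.outcome, e.cause), []).append(e)
    return out


# ---------------------------------------------------------------------------
# core arithmetic


def residual(
    cause_entries: Iterable[EfficacyEntry],
    coverage: Mapping[str, float],
) -> float:
    """Residual mortality fraction for one cause under a coverage vector."""
    r = 1.0
    for e in cause_entries:
        if e.intervention_id not in coverage:
            raise DataError(
                f"no coverage value for intervention {e.intervention_id!r}"
            )
        c = coverage[e.intervention_id]
        if not 0.0 <= c <= 1.0:
            raise DataError(f"coverage {c} outside [0, 1] for {e.intervention_id}")
        r *= 1.0 - e.effect_size * c
    return r


def _coverage_at(trajectories: Mapping[str, Mapping[int, float]], year: int):
    return {iid: vals[year] for iid, vals in trajectories.items()}


def deaths_under(
    trajectories: Mapping[str, Mapping[int, float]],
    epi: EpiProfile,
    config: Iterable[EfficacyEntry],
    baseline_coverage: Mapping[str, float],
) -> pd.DataFrame:
    """Deaths by outcome x cause x year under one scenario's trajectories.

    The baseline envelope (``epi``) is assumed to reflect
    ``baseline_coverage``; deaths for each cause are rescaled by the
    residual ratio. Causes no intervention acts on are unchanged.
    """
    grouped = entries_by_cause(config)
    years = sorted(next(iter(trajectories.values())).keys()) if trajectories else [epi.year]
    rows = []
    for (outcome, cause), d0 in epi.deaths.items():
        entries = grouped.get((outcome, cause), [])
        r0 = residual(entries, baseline_coverage) if entries else 1.0
        if entries and r0 == 0.0:
            raise DataError(
                f"baseline residual is zero for cause ({outcome}, {cause}) "
                "yet observed deaths are positive"
            )
        for year in years:
            if entries:
                ry = residual(entries, _coverage_at(trajectories, year))
                deaths = d0 * ry / r0
            else:
                deaths = d0
            rows.append(
                {"year": year, "outcome": outcome, "cause": cause, "deaths": deaths}
            )
    return pd.DataFrame(rows)


def lives_saved(
    counterfactual_deaths: pd.DataFrame, scenario_deaths: pd.DataFrame
) -> pd.DataFrame:
    """Deaths averted by outcome x cause x year (counterfactual - scenario)."""
    keys = ["year", "outcome", "cause"]
    a = counterfactual_deaths.set_index(keys)["deaths"]
    b = scenario_deaths.set_index(keys)["deaths"]
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise DataError("scenario death tables have mismatched cause lists")
    out = (a - b.reindex(a.index)).reset_index()
    out = out.rename(columns={"deaths": "lives_saved"})
    return out


def attribute_by_intervention(
    cause_entries: list[EfficacyEntry],
    coverage_0: Mapping[str, float],
    coverage_t: Mapping[str, float],
    cause_deaths_0: float,
) -> dict[str, float]:
    """Allocate one cause's joint deaths averted across interventions.

    Single-intervention impacts (only intervention ``i`` moved from its
    baseline coverage) are computed, and the joint total is split
    proportionally to them. The allocations sum to the joint total exactly;
    if no single intervention has any impact, all allocations are zero.
    """
    r0 = residual(cause_entries, coverage_0)
    if r0 == 0.0:
        raise DataError("baseline residual is zero; envelope inconsistent")
    rt = residual(cause_entries, coverage_t)
    joint = cause_deaths_0 * (1.0 - rt / r0)

    singles: dict[str, float] = {}
    for e in cause_entries:
        solo = dict(coverage_0)
        solo[e.intervention_id] = coverage_t[e.intervention_id]
        r_solo = residual(cause_entries, solo)
        singles[e.intervention_id] = cause_deaths_0 * (1.0 - r_solo / r0)

    total_single = sum(singles.values())
    if total_single == 0.0:
        return {iid: 0.0 for iid in singles}
    return {iid: joint * s / total_single for iid, s in singles.items()}


def mortality_rates(
    deaths_by_outcome: Mapping[str, float], epi: EpiProfile
) -> dict[str, float]:
    """MMR (per 100,000 live births), NMR (per 1,000 live births) and
    SBR (per 1,000 total births)."""
    if epi.live_births <= 0 or epi.total_births <= 0:
        raise DataError("birth denominators must be positive")
    return {
        "mmr": deaths_by_outcome["maternal"] / epi.live_births * 1e5,
        "nmr": deaths_by_outcome["neonatal"] / epi.live_births * 1e3,
        "sbr": deaths_by_outcome["stillbirth"] / epi.total_births * 1e3,
    }


# ---------------------------------------------------------------------------
# country-level driver


@dataclass
class ImpactResult:
    """Full impact output for one country."""

    country_id: str
    deaths: pd.DataFrame  # scenario_label, year, outcome, cause, deaths
    lives_saved: pd.DataFrame  # year, outcome, lives_saved
    attribution: pd.DataFrame  # year, outcome, intervention_id, deaths_averted
    rates: pd.DataFrame  # scenario_label, year, mmr, nmr, sbr


def run_country_impact(
    country_id: str,
    scale_up: Mapping[str, Mapping[int, float]],
    counterfactual: Mapping[str, Mapping[int, float]],
    epi: EpiProfile,
    config: Iterable[EfficacyEntry],
) -> ImpactResult:
    """Run both scenarios for one country and derive lives saved, per-
    intervention attribution, and mortality rates.

    The counterfactual trajectories define baseline coverage (they are
    constant at the 2016 baseline by construction).
    """
    config = list(config)
    years = sorted(next(iter(counterfactual.values())).keys())
    base_year = years[0]
    baseline_cov = _coverage_at(counterfactual, base_year)

    cf = deaths_under(counterfactual, epi, config, baseline_cov)
    su = deaths_under(scale_up, epi, config, baseline_cov)
    cf["scenario_label"] = "counterfactual"
    su["scenario_label"] = "scale_up"
    deaths = pd.concat([cf, su], ignore_index=True)

    saved_detail = lives_saved(cf.drop(columns="scenario_label"),
                               su.drop(columns="scenario_label"))
    saved = (
        saved_detail.groupby(["year", "outcome"], as_index=False)["lives_saved"]
        .sum()
    )

    grouped = entries_by_cause(config)
    attr_rows = []
    for (outcome, cause), entries in grouped.items():
        d0 = epi.deaths.get((outcome, cause), 0.0)
        if d0 == 0.0:
            continue
        for year in years:
            alloc = attribute_by_intervention(
                entries, baseline_cov, _coverage_at(scale_up, year), d0
            )
            for iid, averted in alloc.items():
                attr_rows.append(
                    {
                        "year": year,
                        "outcome": outcome,
                        "intervention_id": iid,
                        "deaths_averted": averted,
                    }
                )
    attribution = (
        pd.DataFrame(attr_rows)
        .groupby(["year", "outcome", "intervention_id"], as_index=False)[
            "deaths_averted"
        ]
        .sum()
        if attr_rows
        else pd.DataFrame(
            columns=["year", "outcome", "intervention_id", "deaths_averted"]
        )
    )

    # conservation: attribution must sum to total lives saved per outcome-year
    if len(attribution):
        attr_tot = attribution.groupby(["year", "outcome"])["deaths_averted"].sum()
        saved_tot = saved.set_index(["year", "outcome"])["lives_saved"]
        joined = pd.concat([attr_tot, saved_tot], axis=1).fillna(0.0)
        scale = np.maximum(np.abs(joined["lives_saved"]), 1.0)
        if not (
            np.abs(joined["deaths_averted"] - joined["lives_saved"]) / scale
            < 1e2 * CONSERVATION_RTOL
        ).all():
            raise AssertionError(
                "per-intervention attribution does not sum to total lives saved"
            )

    rate_rows = []
    for label, table in (("counterfactual", cf), ("scale_up", su)):
        for year in years:
            totals = (
                table[table["year"] == year]
                .groupby("outcome")["deaths"]
                .sum()
                .to_dict()
            )
            for o in OUTCOMES:
                totals.setdefault(o, 0.0)
            rate_rows.append(
                {"scenario_label": label, "year": year,
                 **mortality_rates(totals, epi)}
            )
    rates = pd.DataFrame(rate_rows)

    return ImpactResult(
        country_id=country_id,
        deaths=deaths,
        lives_saved=saved,
        attribution=attribution,
        rates=rates,
    )
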