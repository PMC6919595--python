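"""Baseline assembly, quartile imputation, and coverage trajectories.

Countries with a linked facility/household survey pair keep their measured
2016 baselines; countries without one receive the cross-country sample
median (or the 25th/75th percentile in sensitivity runs) for each
intervention. Coverage is then scaled linearly from the 2016 baseline to a
country-specific utilization cap in 2020 (ANC4+ for antenatal
interventions, facility delivery for childbirth and postnatal ones); when
the baseline already exceeds the cap the trajectory is held constant —
coverage is never reduced. The counterfactual freezes coverage at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .linking import EffectiveCoverage, UtilizationProfile
from .registry import (
    ConfigurationError,
    DataError,
    IndicatorDefinition,
    load_registry,
)

START_YEAR = 2016
END_YEAR = 2020
BOUNDS = ("q25", "median", "q75")
_BOUND_PROVENANCE = {"median": "median_proxy", "q25": "q25_proxy", "q75": "q75_proxy"}


def sample_quantiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(q25, median, q75) by linear interpolation of order statistics."""
    if len(values) == 0:
        raise DataError("cannot take quantiles of an empty sample")
    arr = np.asarray(values, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise DataError("coverage values must lie in [0, 1]")
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(q25), float(med), float(q75)


@dataclass
class BaselineTable:
    """Complete 2016 baselines for every country after imputation."""

    bound: str  # which quantile was used for unlinked countries
    quantiles: dict[str, tuple[float, float, float]]  # iid -> (q25, med, q75)
    coverages: dict[str, dict[str, float]]  # country -> iid -> baseline
    provenance: dict[str, dict[str, str]]  # country -> iid -> provenance

    def __post_init__(self) -> None:
        for iid, (q25, med, q75) in self.quantiles.items():
            if not q25 <= med + 1e-12 or not med <= q75 + 1e-12:
                raise DataError(f"crossed quantiles for {iid}: {q25}, {med}, {q75}")


def impute_baselines(
    linked: list[EffectiveCoverage],
    unlinked_countries: Iterable[str],
    bound: str = "median",
    registry: list[IndicatorDefinition] | None = None,
) -> BaselineTable:
    """Fill in baselines for countries without linked surveys.

    Linked countries keep their measured values; the chosen cross-country
    quantile fills unlinked countries and any intervention a linked
    country could not measure (e.g. all components SPA-only under SARA).
    """
    if bound not in BOUNDS:
        raise ConfigurationError(f"bound must be one of {BOUNDS}, got {bound!r}")
    if registry is None:
        registry = load_registry()
    interventions = [d.intervention_id for d in registry]

    pools: dict[str, list[float]] = {iid: [] for iid in interventions}
    for cov in linked:
        for iid, v in cov.values.items():
            pools[iid].append(v)
    empty = [iid for iid, vals in pools.items() if not vals]
    if empty:
        raise DataError(
            f"no linked observation for intervention(s) {empty}; "
            "cannot impute a quantile proxy"
        )
    quantiles = {iid: sample_quantiles(vals) for iid, vals in pools.items()}
    idx = {"q25": 0, "median": 1, "q75": 2}[bound]

    coverages: dict[str, dict[str, float]] = {}
    provenance: dict[str, dict[str, str]] = {}
    proxy_label = _BOUND_PROVENANCE[bound]
    for cov in linked:
        cvals, cprov = {}, {}
        for iid in interventions:
            if iid in cov.values:
                cvals[iid] = cov.values[iid]
                cprov[iid] = "linked"
            else:
                cvals[iid] = quantiles[iid][idx]
                cprov[iid] = proxy_label
        coverages[cov.country_id] = cvals
        provenance[cov.country_id] = cprov
    for cid in unlinked_countries:
        if cid in coverages:
            raise DataError(f"country {cid} is both linked and unlinked")
        coverages[cid] = {iid: quantiles[iid][idx] for iid in interventions}
        provenance[cid] = {iid: proxy_label for iid in interventions}

    return BaselineTable(
        bound=bound, quantiles=quantiles, coverages=coverages, provenance=provenance
    )


def target_for(
    intervention_id: str,
    profile: UtilizationProfile,
    registry: list[IndicatorDefinition] | None = None,
) -> float:
    """2020 utilization cap for one intervention in one country."""
    if registry is None:
        registry = load_registry()
    for d in registry:
        if d.intervention_id == intervention_id:
            return profile.utilization_for(d.period)
    raise ConfigurationError(f"unknown intervention {intervention_id!r}")


@dataclass
class CoverageTrajectory:
    """Annual coverage for one (country, intervention) under one scenario."""

    country_id: str
    intervention_id: str
    values: dict[int, float]
    scenario_label: str

    def __post_init__(self) -> None:
        for y, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise DataError(
                    f"coverage {v} outside [0, 1] at year {y} "
                    f"({self.country_id}/{self.intervention_id})"
                )


def build_trajectory(
    baseline: float,
    target: float,
    start_year: int = START_YEAR,
    end_year: int = END_YEAR,
    country_id: str = "",
    intervention_id: str = "",
    scenario_label: str = "scale_up",
) -> CoverageTrajectory:
    """Linear interpolation from baseline to the utilization cap.

    When the target does not exceed the baseline the trajectory is held
    constant at baseline (coverage is never decreased).
    """
    if end_year <= start_year:
        raise ConfigurationError("end_year must be after start_year")
    for name, v in (("baseline", baseline), ("target", target)):
        if not 0.0 <= v <= 1.0:
            raise DataError(f"{name}={v} outside [0, 1]")
    span = end_year - start_year
    values = {}
    for year in range(start_year, end_year + 1):
        if target > baseline:
            values[year] = baseline + (target - baseline) * (year - start_year) / span
        else:
            values[year] = baseline
    return CoverageTrajectory(
        country_id=country_id,
        intervention_id=intervention_id,
        values=values,
        scenario_label=scenario_label,
    )


def counterfactual(
    baseline: float,
    start_year: int = START_YEAR,
    end_year: int = END_YEAR,
    country_id: str = "",
    intervention_id: str = "",
) -> CoverageTrajectory:
    """Coverage frozen at the 2016 baseline."""
    if not 0.0 <= baseline <= 1.0:
        raise DataError(f"baseline={baseline} outside [0, 1]")
    return CoverageTrajectory(
        country_id=country_id,
        intervention_id=intervention_id,
        values={y: baseline for y in range(start_year, end_year + 1)},
        scenario_label="counterfactual",
    )


def build_country_trajectories(
    country_id: str,
    baselines: dict[str, float],
    profile: UtilizationProfile,
    registry: list[IndicatorDefinition] | None = None,
    scenario_label: str = "scale_up",
) -> tuple[dict[str, CoverageTrajectory], dict[str, CoverageTrajectory]]:
    """(scale_up, counterfactual) trajectory sets for one country."""
    if registry is None:
        registry = load_registry()
    scale, cf = {}, {}
    for d in registry:
        iid = d.intervention_id
        base = baselines[iid]
        target = profile.utilization_for(d.period)
        scale[iid] = build_trajectory(
            base, target, country_id=country_id, intervention_id=iid,
            scenario_label=scenario_label,
        )
        cf[iid] = counterfactual(base, country_id=country_id, intervention_id=iid)
    return scale, cf


def trajectories_to_frame(
    trajectories: Iterable[CoverageTrajectory],
) -> pd.DataFrame:
    rows = [
        {
            "country_id": t.country_id,
            "intervention_id": t.intervention_id,
            "scenario_label": t.scenario_label,
            "year": y,
            "coverage": v,
        }
        for t in trajectories
        for y, v in sorted(t.values.items())
    ]
    return pd.DataFrame(rows)


def write_trajectory_csv(
    trajectories: Iterable[CoverageTrajectory], path: str | Path
) -> pd.DataFrame:
    df = trajectories_to_frame(trajectories)
    df.to_csv(path, index=False)
    return df
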