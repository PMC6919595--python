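"""End-to-end pipeline: link -> impute -> project -> impact -> report.

A run is described by a :class:`RunConfig`, either pointing at input CSVs
or at a synthetic-generation block with a seed. All randomness flows
through that single seed, so repeated runs with the same configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .impact import EpiProfile, ImpactResult, load_efficacy, run_country_impact
from .linking import (
    EffectiveCoverage,
    SurveyPair,
    estimate_country_baseline,
    read_facility_csv,
    read_utilization_csv,
    write_coverage_csv,
)
from .registry import ConfigurationError, load_registry
from .reporting import (
    RunSummary,
    aggregate,
    format_report,
    sensitivity_range,
    write_summary_csv,
)
from .scenario import (
    BOUNDS,
    END_YEAR,
    build_country_trajectories,
    impute_baselines,
    trajectories_to_frame,
)
from .synth import (
    CountryRecord,
    generate_country_set,
    read_epi_csv,
    save_ground_truths,
    write_epi_csv,
    write_utilization_csv,
)

logger = logging.getLogger("careimpact")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``inputs`` (paths to facility/utilization/epi CSVs) or
    ``synthetic`` (generation block; requires ``seed``) must be present.
    """

    synthetic: dict | None = None
    inputs: dict | None = None
    bound: str = "all"  # q25 | median | q75 | all
    efficacy_path: str | None = None
    out_dir: str = "results"
    seed: int | None = None
    log_level: str = "INFO"
    registry_path: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' or 'inputs' must be configured"
            )
        if self.synthetic is not None:
            if self.seed is None:
                raise ConfigurationError("synthetic generation requires a seed")
            if int(self.synthetic.get("n_linked", 17)) < 1:
                raise ConfigurationError(
                    "n_linked must be >= 1: median proxies for unlinked "
                    "countries require at least one linked baseline"
                )
        if self.bound not in BOUNDS + ("all",):
            raise ConfigurationError(f"bound must be one of {BOUNDS + ('all',)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {
            k: raw.pop(k)
            for k in (
                "synthetic", "inputs", "bound", "efficacy_path", "out_dir",
                "seed", "log_level", "registry_path",
            )
            if k in raw
        }
        return cls(**known, extra=raw)


def load_country_records(config: RunConfig) -> list[CountryRecord]:
    """Materialize the study set, either synthetic or from input CSVs."""
    if config.synthetic is not None:
        blk = config.synthetic
        return generate_country_set(
            n_linked=int(blk.get("n_linked", 17)),
            n_unlinked=int(blk.get("n_unlinked", 64)),
            seed=int(config.seed),
            n_facilities=int(blk.get("n_facilities", 400)),
        )
    inp = config.inputs
    profiles = {p.country_id: p for p in read_utilization_csv(inp["utilization"])}
    epis = {e.country_id: e for e in read_epi_csv(inp["epi"])}
    facility_specs = {f["country_id"]: f for f in inp.get("facilities", [])}
    records = []
    for cid, profile in profiles.items():
        if cid not in epis:
            raise ConfigurationError(f"no epi profile for country {cid}")
        pair = None
        if cid in facility_specs:
            spec = facility_specs[cid]
            survey = read_facility_csv(
                spec["path"], spec["survey_type"], float(spec["survey_year"])
            )
            pair = SurveyPair(
                facility_survey=survey,
                household_survey=profile,
                facility_survey_year=float(spec["survey_year"]),
                household_survey_year=float(
                    spec.get("household_year", profile.survey_year)
                ),
            )
        records.append(
            CountryRecord(truth=None, profile=profile, epi=epis[cid], pair=pair)
        )
    return records


def link_stage(
    records: list[CountryRecord], registry
) -> tuple[list[EffectiveCoverage], list[str]]:
    """Estimate baselines for linked countries; list the unlinked ones."""
    linked, unlinked = [], []
    for rec in records:
        if rec.pair is not None:
            linked.append(estimate_country_baseline(rec.pair, registry))
        else:
            unlinked.append(rec.profile.country_id)
    return linked, unlinked


def run_bound(
    records: list[CountryRecord],
    linked: list[EffectiveCoverage],
    unlinked: list[str],
    bound: str,
    registry,
    efficacy,
    year: int = END_YEAR,
) -> tuple[RunSummary, list[ImpactResult], object]:
    """Impute -> project -> impact -> aggregate for a single bound."""
    table = impute_baselines(linked, unlinked, bound=bound, registry=registry)
    results = []
    trajectories = []
    for rec in records:
        cid = rec.profile.country_id
        scale, cf = build_country_trajectories(
            cid, table.coverages[cid], rec.profile, registry=registry
        )
        trajectories.extend(scale.values())
        trajectories.extend(cf.values())
        results.append(
            run_country_impact(
                cid,
                {i: t.values for i, t in scale.items()},
                {i: t.values for i, t in cf.items()},
                rec.epi,
                efficacy,
            )
        )
    summary = aggregate(results, year=year, bound=bound, registry=registry)
    return summary, results, (table, trajectories)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all stage outputs.

    Returns a dict with the per-bound summaries, the sensitivity ranges
    (when all three bounds are run), and the output directory.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(config.registry_path)
    efficacy = load_efficacy(config.efficacy_path)

    records = load_country_records(config)
    logger.info("loaded %d countries", len(records))
    linked, unlinked = link_stage(records, registry)
    logger.info("%d linked, %d unlinked", len(linked), len(unlinked))
    write_coverage_csv(linked, registry, out / "effective_coverage_linked.csv")

    bounds = list(BOUNDS) if config.bound == "all" else [config.bound]
    summaries: dict[str, RunSummary] = {}
    central_results: list[ImpactResult] | None = None
    for bound in bounds:
        summary, results, (table, trajectories) = run_bound(
            records, linked, unlinked, bound, registry, efficacy
        )
        summaries[bound] = summary
        if bound == "median" or len(bounds) == 1:
            central_results = results
            trajectories_frame = trajectories_to_frame(trajectories)
            trajectories_frame.to_csv(out / "coverage_trajectories.csv", index=False)
            deaths = pd.concat(
                [r.deaths.assign(country_id=r.country_id) for r in results],
                ignore_index=True,
            )[["country_id", "scenario_label", "year", "outcome", "cause", "deaths"]]
            deaths.to_csv(out / "deaths_by_cause.csv", index=False)
            attr = pd.concat(
                [r.attribution.assign(country_id=r.country_id) for r in results],
                ignore_index=True,
            )[["country_id", "year", "outcome", "intervention_id", "deaths_averted"]]
            attr.to_csv(out / "lives_saved_by_intervention.csv", index=False)
        write_summary_csv(summary, out / f"summary_{bound}.csv")

    ranges = None
    if set(bounds) == set(BOUNDS):
        ranges = sensitivity_range(summaries)
    central = summaries.get("median", summaries[bounds[0]])
    report = format_report(central, ranges)
    (out / "report.txt").write_text(report, encoding="utf-8")

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "bound": config.bound,
        "n_countries": len(records),
        "n_linked": len(linked),
        "config": {
            "synthetic": config.synthetic,
            "inputs": config.inputs,
            "efficacy_path": config.efficacy_path,
        },
    }
    (out / "provenance.yaml").write_text(
        yaml.safe_dump(provenance, sort_keys=False), encoding="utf-8"
    )
    return {
        "summaries": summaries,
        "ranges": ranges,
        "results": central_results,
        "records": records,
        "out_dir": out,
        "report": report,
    }


def simulate_to_dir(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate a synthetic dataset and write its CSVs plus ground truth."""
    if config.synthetic is None:
        raise ConfigurationError("simulate requires a synthetic block")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = load_country_records(config)
    write_utilization_csv([r.profile for r in records], out / "utilization.csv")
    write_epi_csv([r.epi for r in records], out / "epi.csv")
    manifest = []
    for rec in records:
        if rec.pair is not None:
            cid = rec.profile.country_id
            fname = f"facility_{cid}.csv"
            rec.pair.facility_survey.to_csv(out / fname)
            manifest.append(
                {
                    "country_id": cid,
                    "path": fname,
                    "survey_type": rec.pair.facility_survey.survey_type,
                    "survey_year": rec.pair.facility_survey_year,
                    "household_year": rec.pair.household_survey_year,
                }
            )
    (out / "facilities.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False), encoding="utf-8"
    )
    save_ground_truths(records, out / "ground_truth.yaml")
    return out
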