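"""Aggregate country impact results into global summaries.

Outputs mirror the structure of a multi-country lives-saved analysis:
global totals of lives saved by outcome (with low/central/high scenario
bounds from the quartile-proxy sensitivity runs), percent declines in
mortality rates summarized across countries, and the share of total impact
contributed by antenatal, childbirth, and postnatal interventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .impact import OUTCOMES, ImpactResult
from .registry import DataError, IndicatorDefinition, load_registry
from .scenario import END_YEAR, START_YEAR

PERIOD_ORDER = ("antenatal", "childbirth", "postnatal")


def percent_decline(baseline_rate: float, endline_rate: float) -> float:
    """Percent decline from baseline to endline (negative if it rose)."""
    if baseline_rate <= 0:
        raise DataError("baseline rate must be positive")
    return (baseline_rate - endline_rate) / baseline_rate * 100.0


@dataclass
class RunSummary:
    """Aggregate of one full-sample run under a single scenario bound."""

    bound: str
    year: int
    totals: dict[str, float]  # outcome -> lives saved
    period_shares: dict[str, dict[str, float]]  # 'overall' or outcome -> period -> share
    percent_decline: dict[str, dict[str, float]]  # outcome -> summary stats
    per_country_decline: pd.DataFrame = field(repr=False, default=None)


def aggregate(
    results: list[ImpactResult],
    year: int = END_YEAR,
    bound: str = "median",
    registry: list[IndicatorDefinition] | None = None,
) -> RunSummary:
    """Sum country results into a global summary for one endline year."""
    if registry is None:
        registry = load_registry()
    ids = [r.country_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate country id(s) {dupes}")
    period_of = {d.intervention_id: d.period for d in registry}

    totals = {o: 0.0 for o in OUTCOMES}
    for r in results:
        sub = r.lives_saved[r.lives_saved["year"] == year]
        for row in sub.itertuples(index=False):
            totals[row.outcome] += row.lives_saved

    # period shares from per-intervention attribution
    attr = pd.concat(
        [r.attribution[r.attribution["year"] == year] for r in results],
        ignore_index=True,
    )
    attr["period"] = attr["intervention_id"].map(period_of)
    period_shares: dict[str, dict[str, float]] = {}
    by_outcome = attr.groupby(["outcome", "period"])["deaths_averted"].sum()
    for outcome in OUTCOMES:
        tot = float(by_outcome.get(outcome, pd.Series(dtype=float)).sum())
        shares = {}
        for p in PERIOD_ORDER:
            v = float(by_outcome.get((outcome, p), 0.0))
            shares[p] = v / tot if tot > 0 else 0.0
        period_shares[outcome] = shares
    pooled = attr.groupby("period")["deaths_averted"].sum()
    pooled_tot = float(pooled.sum())
    period_shares["overall"] = {
        p: float(pooled.get(p, 0.0)) / pooled_tot if pooled_tot > 0 else 0.0
        for p in PERIOD_ORDER
    }

    # percent declines in MMR / NMR / SBR per country, summarized across
    # countries by quartiles (and mean, for reference)
    rate_col = {"maternal": "mmr", "neonatal": "nmr", "stillbirth": "sbr"}
    decline_rows = []
    for r in results:
        rates = r.rates.set_index(["scenario_label", "year"])
        base = rates.loc[("counterfactual", START_YEAR)]
        end = rates.loc[("scale_up", year)]
        row = {"country_id": r.country_id}
        for outcome, col in rate_col.items():
            row[outcome] = percent_decline(float(base[col]), float(end[col]))
        decline_rows.append(row)
    per_country = pd.DataFrame(decline_rows)
    declines = {}
    for outcome in OUTCOMES:
        vals = per_country[outcome].to_numpy()
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        declines[outcome] = {
            "q25": float(q25),
            "median": float(med),
            "q75": float(q75),
            "mean": float(vals.mean()),
        }

    return RunSummary(
        bound=bound,
        year=year,
        totals=totals,
        period_shares=period_shares,
        percent_decline=declines,
        per_country_decline=per_country,
    )


@dataclass
class SensitivityRange:
    low: float
    central: float
    high: float
    consistent: bool

    def as_text(self) -> str:
        s = f"{self.central:,.0f} (range, {self.low:,.0f}-{self.high:,.0f})"
        if not self.consistent:
            s += " [INCONSISTENT BOUNDS]"
        return s


def sensitivity_range(
    runs: Mapping[str, RunSummary],
) -> dict[str, SensitivityRange]:
    """Low/central/high lives-saved totals from the q25/median/q75 runs.

    The quantile bounds apply to *starting* coverage: a higher starting
    baseline (q75 proxy) leaves less headroom below the fixed utilization
    cap and therefore fewer lives saved, so the q75 run supplies the low
    end of the range and the q25 run the high end. Ordering is verified,
    never assumed: a crossed range (which can arise from the no-decrease
    cap rule interacting with low utilization caps) is flagged, not
    silently reordered.
    """
    for b in ("q25", "median", "q75"):
        if b not in runs:
            raise DataError(f"missing {b} run for sensitivity range")
    out = {}
    for outcome in OUTCOMES:
        low = runs["q75"].totals[outcome]
        central = runs["median"].totals[outcome]
        high = runs["q25"].totals[outcome]
        out[outcome] = SensitivityRange(
            low=low,
            central=central,
            high=high,
            consistent=low <= central + 1e-9 and central <= high + 1e-9,
        )
    return out


# ---------------------------------------------------------------------------
# serialisation and figures


def summary_to_frame(summary: RunSummary) -> pd.DataFrame:
    rows = []
    for outcome, total in summary.totals.items():
        rows.append({"quantity": "lives_saved", "outcome": outcome,
                     "period": "", "value": total})
    for scope, shares in summary.period_shares.items():
        for p, v in shares.items():
            rows.append({"quantity": "period_share", "outcome": scope,
                         "period": p, "value": v})
    for outcome, stats in summary.percent_decline.items():
        for stat, v in stats.items():
            rows.append({"quantity": f"rate_decline_{stat}", "outcome": outcome,
                         "period": "", "value": v})
    return pd.DataFrame(rows)


def write_summary_csv(summary: RunSummary, path: str | Path) -> pd.DataFrame:
    df = summary_to_frame(summary)
    df.to_csv(path, index=False)
    return df


def format_report(
    central: RunSummary,
    ranges: Mapping[str, SensitivityRange] | None = None,
) -> str:
    """Human-readable text report of the global summary."""
    lines = [
        f"Global impact summary, endline year {central.year}",
        "=" * 48,
        "",
        "Lives saved / stillbirths prevented:",
    ]
    label = {"maternal": "maternal lives saved",
             "neonatal": "neonatal lives saved",
             "stillbirth": "stillbirths prevented"}
    for outcome in OUTCOMES:
        if ranges is not None:
            lines.append(f"  {label[outcome]:<26}: {ranges[outcome].as_text()}")
        else:
            lines.append(f"  {label[outcome]:<26}: {central.totals[outcome]:,.0f}")
    lines += ["", "Median percent decline in mortality rates (IQR across countries):"]
    rate_name = {"maternal": "MMR", "neonatal": "NMR", "stillbirth": "SBR"}
    for outcome in OUTCOMES:
        d = central.percent_decline[outcome]
        lines.append(
            f"  {rate_name[outcome]}: {d['median']:.1f}% "
            f"({d['q25']:.1f}% to {d['q75']:.1f}%)"
        )
    lines += ["", "Share of total impact by care period:"]
    for p in PERIOD_ORDER:
        lines.append(f"  {p:<12}: {central.period_shares['overall'][p]:.1%}")
    for outcome in OUTCOMES:
        shares = central.period_shares[outcome]
        parts = ", ".join(f"{p} {shares[p]:.0%}" for p in PERIOD_ORDER)
        lines.append(f"    {outcome:<10}: {parts}")
    return "\n".join(lines) + "\n"


def plot_impact_by_period(summary: RunSummary, results: list[ImpactResult],
                          path: str | Path,
                          registry: list[IndicatorDefinition] | None = None):
    """Bar chart of lives saved by care period and outcome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if registry is None:
        registry = load_registry()
    period_of = {d.intervention_id: d.period for d in registry}
    attr = pd.concat(
        [r.attribution[r.attribution["year"] == summary.year] for r in results],
        ignore_index=True,
    )
    attr["period"] = attr["intervention_id"].map(period_of)
    table = attr.pivot_table(index="period", columns="outcome",
                             values="deaths_averted", aggfunc="sum").reindex(
        list(PERIOD_ORDER)
    )
    ax = table.plot.bar(figsize=(7, 4))
    ax.set_ylabel("deaths averted in endline year")
    ax.set_xlabel("care period")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)


def plot_rate_decline_box(summary: RunSummary, path: str | Path):
    """Boxplot of per-country percent declines in MMR, NMR, SBR."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.per_country_decline
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([df[o] for o in OUTCOMES], tick_labels=["MMR", "NMR", "SBR"])
    ax.set_ylabel("percent decline, endline vs baseline")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
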