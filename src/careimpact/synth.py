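"""Synthetic facility, household, and epidemiological data with known truth.

The generator emulates the three data sources the pipeline links:

* facility surveys (SPA/SARA-style component checklists, with strata and
  survey weights),
* household utilization profiles (ANC4+ and facility-delivery proportions,
  shares of care contacts by facility stratum),
* epidemiological envelopes (live births, stillbirths, cause-specific
  maternal/neonatal/stillbirth death counts).

Component availability is generated from independent per-component Bernoulli
probabilities solved so that, for every intervention, the probability that a
facility has *all* required components equals the intervention's ground-truth
readiness probability. Each intervention carries one scarce "binding"
component; components shared across interventions (guidelines, staff
training) are treated as universally present unless they are another
intervention's binding component. Because the induction-of-labor checklist
is a subset of the AMTSL checklist, their readiness probabilities are not
free: the generator requires readiness(AMTSL) <= readiness(induction) and
reports the exact closed-form conjunction probability for every
intervention, stratum, and survey type via ``GroundTruth.expected_readiness``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .impact import CAUSES, OUTCOMES, EpiProfile
from .linking import FacilitySurvey, SurveyPair, UtilizationProfile
from .registry import (
    ConfigurationError,
    IndicatorDefinition,
    load_registry,
    registry_components,
)

DEFAULT_STRATA = ("hospital", "health_center", "clinic")

#: readiness multiplier by stratum: hospitals are best equipped, small
#: clinics least (applied to the binding-component probability)
_STRATUM_MULTIPLIER = {"hospital": 1.0, "health_center": 0.85, "clinic": 0.70}

#: Dirichlet concentration for cause-of-death fractions (rough global
#: cause-structure shapes, scaled to moderate variability)
_CAUSE_ALPHA = {
    "maternal": {
        "hemorrhage": 3.2,
        "hypertensive_disorders": 1.7,
        "sepsis": 1.3,
        "obstructed_labor": 1.1,
        "other_maternal": 4.7,
    },
    "neonatal": {
        "prematurity": 4.2,
        "intrapartum_related": 2.9,
        "sepsis": 1.8,
        "pneumonia": 0.7,
        "tetanus": 0.3,
        "other_neonatal": 2.1,
    },
    "stillbirth": {"antepartum": 6.6, "intrapartum": 5.4},
}


# ---------------------------------------------------------------------------
# binding-component scheme


def assign_binding_components(
    registry: list[IndicatorDefinition],
) -> dict[str, str]:
    """Choose one binding component per intervention.

    The binding component is the rarest-shared component in the checklist
    (preferring components unique to the intervention and assessed in both
    survey types). Two interventions may not share a binding component.
    """
    counts: dict[str, int] = {}
    for d in registry:
        for c in d.required_components:
            counts[c] = counts.get(c, 0) + 1
    binding: dict[str, str] = {}
    for d in registry:
        spa_only = set(d.spa_only_components)
        ranked = sorted(
            d.required_components,
            key=lambda c: (counts[c], c in spa_only, d.required_components.index(c)),
        )
        binding[d.intervention_id] = ranked[0]
    seen: dict[str, str] = {}
    for iid, comp in binding.items():
        if comp in seen:
            raise ConfigurationError(
                f"interventions {seen[comp]} and {iid} resolve to the same "
                f"binding component {comp!r}; registry not generatable"
            )
        seen[comp] = iid
    return binding


def solve_component_probs(
    registry: list[IndicatorDefinition],
    readiness: dict[str, float],
) -> dict[str, float]:
    """Per-component Bernoulli probabilities matching target conjunctions.

    Solves independent probabilities ``p_c`` such that for every
    intervention ``i``, ``prod_{c in checklist_i} p_c == readiness[i]``.
    Non-binding components default to probability 1. Raises a
    ``ConfigurationError`` when the targets are infeasible (e.g. an
    intervention whose checklist is a superset of another's but whose
    readiness target is higher).
    """
    binding = assign_binding_components(registry)
    binding_comps = set(binding.values())
    probs: dict[str, float] = {
        c: 1.0 for c in registry_components(registry) if c not in binding_comps
    }

    pending = {d.intervention_id: d for d in registry}
    while pending:
        progressed = False
        for iid in list(pending):
            d = pending[iid]
            b = binding[iid]
            others = [c for c in d.required_components if c != b]
            if any(c not in probs for c in others):
                continue  # depends on a binding component not yet solved
            prod_others = float(np.prod([probs[c] for c in others])) if others else 1.0
            target = readiness[iid]
            if not 0.0 <= target <= 1.0:
                raise ConfigurationError(
                    f"readiness_prob[{iid}]={target} outside [0, 1]"
                )
            if prod_others == 0.0:
                if target > 1e-12:
                    raise ConfigurationError(
                        f"{iid}: a shared required component has probability 0 "
                        f"but readiness target is {target}"
                    )
                probs[b] = 1.0
            else:
                q = target / prod_others
                if q > 1.0 + 1e-9:
                    raise ConfigurationError(
                        f"{iid}: readiness target {target} infeasible; its "
                        f"checklist shares components constraining the joint "
                        f"probability to at most {prod_others:.6g}"
                    )
                probs[b] = min(q, 1.0)
            del pending[iid]
            progressed = True
        if not progressed:
            raise ConfigurationError(
                f"cyclic binding-component dependencies among {sorted(pending)}"
            )
    return probs


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """All latent parameters behind one synthetic country."""

    country_id: str
    readiness_prob: dict[str, dict[str, float]]  # intervention -> stratum -> p
    anc4_plus: float
    hfd: float
    stratum_shares: dict[str, float]
    live_births: int
    stillbirths: int
    cause_fractions: dict[str, dict[str, float]]  # outcome -> cause -> frac
    baseline_deaths: dict[str, int]  # outcome -> count
    _component_probs: dict[str, dict[str, float]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for v, name in ((self.anc4_plus, "anc4_plus"), (self.hfd, "hfd")):
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.stratum_shares.values()) - 1.0) > 1e-9:
            raise ConfigurationError("stratum shares must sum to 1")
        for iid, by_stratum in self.readiness_prob.items():
            for s, p in by_stratum.items():
                if s not in self.stratum_shares:
                    raise ConfigurationError(
                        f"readiness_prob[{iid}] references unknown stratum {s!r}"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"readiness_prob[{iid}][{s}]={p} outside [0, 1]"
                    )
        for outcome, fracs in self.cause_fractions.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"cause fractions for {outcome} sum to {total}"
                )
        for name, v in (
            ("live_births", self.live_births),
            ("stillbirths", self.stillbirths),
            *((f"baseline_deaths[{o}]", n) for o, n in self.baseline_deaths.items()),
        ):
            if v < 0 or int(v) != v:
                raise ConfigurationError(f"{name}={v} must be a nonnegative integer")

    @property
    def strata(self) -> tuple[str, ...]:
        return tuple(self.stratum_shares)

    def component_probs(
        self, registry: list[IndicatorDefinition] | None = None
    ) -> dict[str, dict[str, float]]:
        """stratum -> component -> Bernoulli probability (cached)."""
        if self._component_probs is None:
            if registry is None:
                registry = load_registry()
            self._component_probs = {
                s: solve_component_probs(
                    registry,
                    {iid: ps[s] for iid, ps in self.readiness_prob.items()},
                )
                for s in self.strata
            }
        return self._component_probs

    def expected_readiness(
        self,
        intervention_id: str,
        stratum: str,
        survey_type: str = "SPA",
        registry: list[IndicatorDefinition] | None = None,
    ) -> float | None:
        """Closed-form probability a facility is fully ready.

        Under SARA, SPA-only components drop out of the conjunction, so the
        expected readiness can exceed the nominal readiness probability
        (e.g. indicators whose only scarce component is SPA-only reduce to
        the shared-guideline probability). Returns None when the indicator
        has no assessable components under the survey type.
        """
        if registry is None:
            registry = load_registry()
        probs = self.component_probs(registry)[stratum]
        definition = next(
            d for d in registry if d.intervention_id == intervention_id
        )
        applicable = definition.applicable_components(survey_type)
        if not applicable:
            return None
        return float(np.prod([probs[c] for c in applicable]))

    def expected_coverage(
        self,
        intervention_id: str,
        survey_type: str = "SPA",
        registry: list[IndicatorDefinition] | None = None,
    ) -> float | None:
        """Ground-truth effective coverage: U x sum_s share_s x readiness_s."""
        if registry is None:
            registry = load_registry()
        definition = next(
            d for d in registry if d.intervention_id == intervention_id
        )
        acc = 0.0
        for s, share in self.stratum_shares.items():
            r = self.expected_readiness(intervention_id, s, survey_type, registry)
            if r is None:
                return None
            acc += share * r
        util = self.anc4_plus if definition.period == "antenatal" else self.hfd
        return util * acc


def sample_ground_truth(
    country_id: str,
    rng: np.random.Generator,
    strata: tuple[str, ...] = DEFAULT_STRATA,
    registry: list[IndicatorDefinition] | None = None,
) -> GroundTruth:
    """Draw a random but internally consistent country ground truth.

    Readiness is built forward from binding-component probabilities (base
    availability uniform on [0.35, 0.95], degraded for lower facility
    strata), which guarantees the conjunction targets are feasible.
    Utilization levels are beta-distributed around the low-to-moderate
    levels typical of high-burden settings (ANC4+ mean ~0.60, facility
    delivery mean ~0.66).
    """
    if registry is None:
        registry = load_registry()
    binding = assign_binding_components(registry)
    binding_probs = {
        iid: float(rng.uniform(0.35, 0.95)) for iid in binding
    }
    comps = registry_components(registry)
    readiness_prob: dict[str, dict[str, float]] = {}
    for d in registry:
        readiness_prob[d.intervention_id] = {}
    for s in strata:
        mult = _STRATUM_MULTIPLIER.get(s, 0.8)
        p = {c: 1.0 for c in comps}
        for iid, b in binding.items():
            p[b] = float(np.clip(binding_probs[iid] * mult, 0.02, 0.98))
        for d in registry:
            readiness_prob[d.intervention_id][s] = float(
                np.prod([p[c] for c in d.required_components])
            )

    anc4 = float(np.clip(rng.beta(3.6, 2.4), 0.06, 0.96))
    hfd = float(np.clip(rng.beta(3.3, 1.7), 0.09, 0.99))
    shares = rng.dirichlet([4.0, 3.0, 2.0][: len(strata)] or [1.0])
    stratum_shares = {s: float(v) for s, v in zip(strata, shares)}
    # renormalise away float residue
    total = sum(stratum_shares.values())
    stratum_shares = {s: v / total for s, v in stratum_shares.items()}

    live_births = int(round(np.exp(rng.uniform(np.log(5e4), np.log(2e6)))))
    sbr = rng.uniform(10.0, 30.0)  # stillbirths per 1,000 total births
    stillbirths = int(round(live_births * sbr / (1000.0 - sbr)))
    mmr = rng.uniform(100.0, 800.0)
    nmr = rng.uniform(15.0, 45.0)
    baseline_deaths = {
        "maternal": int(round(live_births * mmr / 1e5)),
        "neonatal": int(round(live_births * nmr / 1e3)),
        "stillbirth": stillbirths,
    }
    cause_fractions = {}
    for outcome in OUTCOMES:
        alphas = _CAUSE_ALPHA[outcome]
        draw = rng.dirichlet(np.array(list(alphas.values())) * 4.0)
        fr = {c: float(v) for c, v in zip(alphas, draw)}
        fr = {c: v / sum(fr.values()) for c, v in fr.items()}
        cause_fractions[outcome] = fr

    return GroundTruth(
        country_id=country_id,
        readiness_prob=readiness_prob,
        anc4_plus=anc4,
        hfd=hfd,
        stratum_shares=stratum_shares,
        live_births=live_births,
        stillbirths=stillbirths,
        cause_fractions=cause_fractions,
        baseline_deaths=baseline_deaths,
    )


# ---------------------------------------------------------------------------
# survey generation


def _allocate_strata(shares: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation; every nonzero-share stratum gets >= 1
    facility when n allows."""
    items = [(s, sh) for s, sh in shares.items() if sh > 0]
    raw = {s: sh * n for s, sh in items}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    rem = n - sum(counts.values())
    for s, _ in sorted(raw.items(), key=lambda kv: kv[1] - np.floor(kv[1]),
                       reverse=True)[:rem]:
        counts[s] += 1
    if n >= len(items):
        for s, _ in items:
            if counts[s] == 0:
                donor = max(counts, key=counts.get)
                counts[donor] -= 1
                counts[s] = 1
    return counts


def generate_facility_survey(
    truth: GroundTruth,
    n_facilities: int,
    survey_type: str,
    seed: int,
    survey_year: float = 2014.0,
    weight_style: str = "constant",
    registry: list[IndicatorDefinition] | None = None,
) -> FacilitySurvey:
    """Draw a facility survey consistent with the ground truth.

    Every component referenced by the registry gets a 0/1 column. Weights
    are 1.0 by default; ``weight_style="gamma"`` draws gamma(4, 1/4)
    weights (mean 1) to exercise weighted estimation.
    """
    if seed is None:
        raise ConfigurationError("a seed is required; no implicit global RNG")
    if n_facilities < 1:
        raise ConfigurationError("n_facilities must be >= 1")
    if registry is None:
        registry = load_registry()
    rng = np.random.default_rng(seed)
    comps = registry_components(registry)
    probs = truth.component_probs(registry)
    counts = _allocate_strata(truth.stratum_shares, n_facilities)

    frames = []
    offset = 0
    for stratum in truth.strata:
        n_s = counts.get(stratum, 0)
        if n_s == 0:
            continue
        p_vec = np.array([probs[stratum][c] for c in comps])
        draws = rng.random((n_s, len(comps))) < p_vec
        if weight_style == "constant":
            w = np.ones(n_s)
        elif weight_style == "gamma":
            w = rng.gamma(shape=4.0, scale=0.25, size=n_s)
        else:
            raise ConfigurationError(f"unknown weight_style {weight_style!r}")
        df = pd.DataFrame(draws.astype(int), columns=comps)
        df.insert(0, "weight", w)
        df.insert(0, "stratum", stratum)
        df.insert(
            0,
            "facility_id",
            [f"{truth.country_id}_F{offset + i + 1:05d}" for i in range(n_s)],
        )
        offset += n_s
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    return FacilitySurvey(
        records=records, survey_type=survey_type, survey_year=survey_year
    )


def generate_household_survey(
    truth: GroundTruth,
    seed: int,
    noise_sd: float = 0.0,
    survey_year: float = 2014.0,
) -> UtilizationProfile:
    """Emit the country's utilization profile, optionally with sampling
    noise (Gaussian, clipped to [0, 1]) on ANC4+ and facility delivery.
    Stratum shares are emitted exactly."""
    if seed is None:
        raise ConfigurationError("a seed is required; no implicit global RNG")
    rng = np.random.default_rng(seed)
    anc4 = truth.anc4_plus
    hfd = truth.hfd
    if noise_sd > 0:
        anc4 = float(np.clip(anc4 + rng.normal(0.0, noise_sd), 0.0, 1.0))
        hfd = float(np.clip(hfd + rng.normal(0.0, noise_sd), 0.0, 1.0))
    return UtilizationProfile(
        country_id=truth.country_id,
        anc4_plus=anc4,
        hfd=hfd,
        stratum_shares=dict(truth.stratum_shares),
        survey_year=survey_year,
    )


def generate_epi_profile(truth: GroundTruth, year: int = 2016) -> EpiProfile:
    """Cause-specific death envelope implied by the ground truth."""
    deaths = {
        (outcome, cause): truth.baseline_deaths[outcome] * frac
        for outcome, fracs in truth.cause_fractions.items()
        for cause, frac in fracs.items()
    }
    return EpiProfile(
        country_id=truth.country_id,
        year=year,
        live_births=float(truth.live_births),
        total_births=float(truth.live_births + truth.stillbirths),
        deaths=deaths,
    )


@dataclass
class CountryRecord:
    """One study country: profiles plus, for linked countries, its surveys.

    ``truth`` is populated for synthetic countries and None for countries
    loaded from input CSVs."""

    truth: GroundTruth | None
    profile: UtilizationProfile
    epi: EpiProfile
    pair: SurveyPair | None = None

    @property
    def is_linked(self) -> bool:
        return self.pair is not None


def generate_country_set(
    n_linked: int,
    n_unlinked: int,
    seed: int,
    n_facilities: int = 400,
    registry: list[IndicatorDefinition] | None = None,
) -> list[CountryRecord]:
    """Generate a multi-country study set.

    Linked countries carry a facility survey (alternating SPA and SARA)
    paired with a household survey at most two years apart; unlinked
    countries carry only utilization and epidemiological profiles.
    """
    if seed is None:
        raise ConfigurationError("a seed is required; no implicit global RNG")
    if n_linked + n_unlinked == 0:
        raise ConfigurationError("need at least one country")
    if registry is None:
        registry = load_registry()
    rng = np.random.default_rng(seed)
    records: list[CountryRecord] = []
    total = n_linked + n_unlinked
    for k in range(total):
        cid = f"C{k + 1:03d}"
        truth = sample_ground_truth(cid, rng, registry=registry)
        hh_seed = int(rng.integers(0, 2**31 - 1))
        fac_seed = int(rng.integers(0, 2**31 - 1))
        epi = generate_epi_profile(truth)
        if k < n_linked:
            survey_type = "SPA" if k % 2 == 0 else "SARA"
            fac_year = float(rng.integers(2007, 2016))
            gap = float(rng.choice([-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0]))
            hh_year = float(np.clip(fac_year + gap, 2005.0, 2016.0))
            profile = generate_household_survey(truth, hh_seed, survey_year=hh_year)
            survey = generate_facility_survey(
                truth, n_facilities, survey_type, fac_seed,
                survey_year=fac_year, registry=registry,
            )
            pair = SurveyPair(
                facility_survey=survey,
                household_survey=profile,
                facility_survey_year=fac_year,
                household_survey_year=hh_year,
            )
            records.append(CountryRecord(truth=truth, profile=profile,
                                         epi=epi, pair=pair))
        else:
            profile = generate_household_survey(truth, hh_seed)
            records.append(CountryRecord(truth=truth, profile=profile, epi=epi))
    return records


# ---------------------------------------------------------------------------
# serialisation


def write_utilization_csv(profiles: list[UtilizationProfile], path: str | Path):
    rows = []
    for p in profiles:
        for stratum, share in p.stratum_shares.items():
            rows.append(
                {
                    "country_id": p.country_id,
                    "anc4_plus": p.anc4_plus,
                    "hfd": p.hfd,
                    "stratum": stratum,
                    "stratum_share": share,
                    "survey_year": p.survey_year,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_epi_csv(profiles: list[EpiProfile], path: str | Path):
    rows = []
    for e in profiles:
        rows.append({"country_id": e.country_id, "outcome": "births",
                     "cause": "live_births", "deaths": e.live_births})
        rows.append({"country_id": e.country_id, "outcome": "births",
                     "cause": "total_births", "deaths": e.total_births})
        for (outcome, cause), v in e.deaths.items():
            rows.append({"country_id": e.country_id, "outcome": outcome,
                         "cause": cause, "deaths": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_epi_csv(path: str | Path, year: int = 2016) -> list[EpiProfile]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("country_id", sort=False):
        births = grp[grp["outcome"] == "births"].set_index("cause")["deaths"]
        deaths = {
            (str(r.outcome), str(r.cause)): float(r.deaths)
            for r in grp[grp["outcome"] != "births"].itertuples(index=False)
        }
        out.append(
            EpiProfile(
                country_id=str(cid),
                year=year,
                live_births=float(births["live_births"]),
                total_births=float(births["total_births"]),
                deaths=deaths,
            )
        )
    return out


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "country_id": truth.country_id,
        "readiness_prob": truth.readiness_prob,
        "anc4_plus": truth.anc4_plus,
        "hfd": truth.hfd,
        "stratum_shares": truth.stratum_shares,
        "live_births": truth.live_births,
        "stillbirths": truth.stillbirths,
        "cause_fractions": truth.cause_fractions,
        "baseline_deaths": truth.baseline_deaths,
    }


def save_ground_truths(records: list[CountryRecord], path: str | Path):
    payload = [ground_truth_to_dict(r.truth) for r in records]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
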