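import itertools

import numpy as np
import pandas as pd
import pytest

from careimpact.impact import (
    CAUSES,
    EfficacyEntry,
    EpiProfile,
    attribute_by_intervention,
    deaths_under,
    lives_saved,
    load_efficacy,
    mortality_rates,
    residual,
    run_country_impact,
)
from careimpact.registry import DataError


def entry(iid, outcome="neonatal", cause="sepsis", eff=0.5, af=1.0):
    return EfficacyEntry(iid, outcome, cause, eff, af)


def simple_epi(deaths=None, live=100_000.0, total=102_000.0):
    deaths = deaths or {("neonatal", "sepsis"): 1000.0}
    return EpiProfile("X", 2016, live, total, deaths)


class TestResidual:
    def test_empty_product_is_one(self):
        assert residual([], {}) == 1.0

    def test_single_entry_closed_form(self):
        assert residual([entry("a", eff=0.5, af=1.0)], {"a": 0.6}) == pytest.approx(0.70)

    def test_two_entry_product(self):
        entries = [entry("a", eff=0.5), entry("b", eff=0.4)]
        r = residual(entries, {"a": 1.0, "b": 1.0})
        assert r == pytest.approx(0.30)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        entries = [entry(f"i{k}", eff=rng.random(), af=rng.random())
                   for k in range(5)]
        cov = {f"i{k}": rng.random() for k in range(5)}
        ref = residual(entries, cov)
        for perm in itertools.permutations(entries):
            assert residual(list(perm), cov) == pytest.approx(ref, rel=1e-12)

    def test_missing_coverage_is_error(self):
        with pytest.raises(DataError, match="a"):
            residual([entry("a")], {"b": 0.5})


class TestDeathsUnder:
    def test_residual_ratio_closed_form(self):
        """1000 baseline deaths, coverage 0.2 -> 0.6 with efficacy 0.5:
        deaths scale by 0.70/0.90."""
        config = [entry("a", eff=0.5, af=1.0)]
        traj = {"a": {2016: 0.2, 2020: 0.6}}
        out = deaths_under(traj, simple_epi(), config, {"a": 0.2})
        d2020 = out[(out.year == 2020)]["deaths"].iloc[0]
        assert d2020 == pytest.approx(1000 * 0.70 / 0.90)

    def test_unchanged_coverage_unchanged_deaths(self):
        config = [entry("a")]
        traj = {"a": {2016: 0.3, 2020: 0.3}}
        out = deaths_under(traj, simple_epi(), config, {"a": 0.3})
        assert (out["deaths"] == 1000.0).all()

    def test_full_aversion_limit(self):
        config = [entry("a", eff=1.0, af=1.0)]
        traj = {"a": {2016: 0.5, 2020: 1.0}}
        out = deaths_under(traj, simple_epi(), config, {"a": 0.5})
        assert out[out.year == 2020]["deaths"].iloc[0] == pytest.approx(0.0)

    def test_untouched_cause_unchanged(self):
        epi = simple_epi({("neonatal", "sepsis"): 1000.0,
                          ("maternal", "hemorrhage"): 500.0})
        config = [entry("a")]
        traj = {"a": {2016: 0.0, 2020: 1.0}}
        out = deaths_under(traj, epi, config, {"a": 0.0})
        mat = out[out.outcome == "maternal"]
        assert (mat["deaths"] == 500.0).all()

    def test_zero_baseline_residual_is_error(self):
        config = [entry("a", eff=1.0, af=1.0)]
        traj = {"a": {2016: 1.0, 2020: 1.0}}
        with pytest.raises(DataError, match="residual"):
            deaths_under(traj, simple_epi(), config, {"a": 1.0})


class TestLivesSaved:
    def test_identical_scenarios_zero(self):
        config = [entry("a")]
        traj = {"a": {2016: 0.3, 2020: 0.3}}
        d = deaths_under(traj, simple_epi(), config, {"a": 0.3})
        out = lives_saved(d, d.copy())
        assert (out["lives_saved"] == 0.0).all()

    def test_worked_difference(self):
        config = [entry("a", eff=0.5, af=1.0)]
        cf = deaths_under({"a": {2020: 0.2}}, simple_epi(), config, {"a": 0.2})
        su = deaths_under({"a": {2020: 0.6}}, simple_epi(), config, {"a": 0.2})
        out = lives_saved(cf, su)
        assert out["lives_saved"].iloc[0] == pytest.approx(1000 - 1000 * 0.7 / 0.9)

    def test_untouched_cause_bounds_savings(self):
        epi = simple_epi({("neonatal", "sepsis"): 500.0,
                          ("neonatal", "tetanus"): 500.0})
        config = [entry("a", cause="sepsis", eff=1.0)]
        cf = deaths_under({"a": {2020: 0.0}}, epi, config, {"a": 0.0})
        su = deaths_under({"a": {2020: 1.0}}, epi, config, {"a": 0.0})
        total = lives_saved(cf, su)["lives_saved"].sum()
        assert total <= 500.0 + 1e-9

    def test_mismatched_causes_rejected(self):
        a = pd.DataFrame({"year": [2020], "outcome": ["neonatal"],
                          "cause": ["sepsis"], "deaths": [1.0]})
        b = a.assign(cause=["tetanus"])
        with pytest.raises(DataError):
            lives_saved(a, b)


class TestAttribution:
    def test_single_intervention_gets_joint_total(self):
        entries = [entry("a", eff=0.5)]
        alloc = attribute_by_intervention(entries, {"a": 0.2}, {"a": 0.6}, 1000.0)
        assert alloc["a"] == pytest.approx(1000 * (1 - 0.7 / 0.9))

    def test_proportional_allocation_oracle(self):
        """Construct entries whose single-intervention impacts are 500 and
        400, then check the joint total splits 5:4."""
        d0 = 1000.0
        # efficacies chosen so solo impacts are exactly 500 and 400 from
        # coverage 0 -> 1: impact_i = d0 * e_i
        entries = [entry("a", eff=0.5), entry("b", eff=0.4)]
        cov0 = {"a": 0.0, "b": 0.0}
        cov1 = {"a": 1.0, "b": 1.0}
        joint = d0 * (1 - 0.5 * 0.6)  # 700
        alloc = attribute_by_intervention(entries, cov0, cov1, d0)
        assert alloc["a"] == pytest.approx(joint * 500 / 900)
        assert alloc["b"] == pytest.approx(joint * 400 / 900)
        assert sum(alloc.values()) == pytest.approx(joint, rel=1e-12)

    def test_zero_change_zero_allocation(self):
        entries = [entry("a"), entry("b")]
        cov = {"a": 0.4, "b": 0.2}
        alloc = attribute_by_intervention(entries, cov, dict(cov), 1000.0)
        assert all(v == 0.0 for v in alloc.values())

    def test_joint_never_exceeds_sum_of_singles(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(1, 4))
            entries = [entry(f"i{j}", eff=rng.uniform(0.1, 0.9),
                             af=rng.uniform(0.1, 1.0)) for j in range(k)]
            cov0 = {f"i{j}": rng.uniform(0, 0.5) for j in range(k)}
            cov1 = {f"i{j}": rng.uniform(cov0[f"i{j}"], 1.0) for j in range(k)}
            r0 = residual(entries, cov0)
            joint = 1000 * (1 - residual(entries, cov1) / r0)
            singles = []
            for e in entries:
                solo = dict(cov0, **{e.intervention_id: cov1[e.intervention_id]})
                singles.append(1000 * (1 - residual(entries, solo) / r0))
            assert joint <= sum(singles) + 1e-9
            if k == 1:
                assert joint == pytest.approx(singles[0], rel=1e-12)


class TestMortalityRates:
    def test_definitions(self):
        epi = simple_epi(live=100_000.0, total=101_800.0)
        rates = mortality_rates(
            {"maternal": 150.0, "neonatal": 2000.0, "stillbirth": 1800.0}, epi
        )
        assert rates["mmr"] == pytest.approx(150.0)
        assert rates["nmr"] == pytest.approx(20.0)
        assert rates["sbr"] == pytest.approx(1800.0 / 101_800.0 * 1000)

    def test_zero_denominator_rejected(self):
        epi = EpiProfile("X", 2016, 0.0, 0.0, {})
        with pytest.raises(DataError):
            mortality_rates({"maternal": 1, "neonatal": 1, "stillbirth": 1}, epi)


def brute_force_deaths(trajectories, epi, config, baseline_cov):
    """Independent oracle: per cause-year, explicitly multiply the residual
    factors and rescale the envelope."""
    out = {}
    for (outcome, cause), d0 in epi.deaths.items():
        entries = [e for e in config if (e.outcome, e.cause) == (outcome, cause)]
        r0 = 1.0
        for e in entries:
            r0 *= 1 - e.efficacy * e.affected_fraction * baseline_cov[e.intervention_id]
        years = sorted(next(iter(trajectories.values())).keys())
        for y in years:
            ry = 1.0
            for e in entries:
                ry *= (1 - e.efficacy * e.affected_fraction
                       * trajectories[e.intervention_id][y])
            out[(outcome, cause, y)] = d0 * (ry / r0 if entries else 1.0)
    return out


class TestEngineOracleEquivalence:
    def test_randomized_small_instances_match_brute_force(self):
        """200 random instances with <=3 causes and <=3 interventions agree
        with an independent residual-ratio implementation to 1e-9 relative,
        and attribution sums to the joint total."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n_int = int(rng.integers(1, 4))
            n_cause = int(rng.integers(1, 4))
            causes = [("neonatal", c) for c in
                      list(CAUSES["neonatal"])[:n_cause]]
            iids = [f"i{k}" for k in range(n_int)]
            config = []
            for (o, c) in causes:
                for iid in iids:
                    if rng.random() < 0.7:
                        config.append(EfficacyEntry(
                            iid, o, c, float(rng.uniform(0, 0.9)),
                            float(rng.uniform(0.1, 1.0))))
            epi = EpiProfile("X", 2016, 1e5, 1.02e5,
                             {k: float(rng.uniform(10, 2000)) for k in causes})
            base = {iid: float(rng.uniform(0, 0.8)) for iid in iids}
            traj = {
                iid: {2016: base[iid],
                      2020: float(rng.uniform(base[iid], 1.0))}
                for iid in iids
            }
            result = deaths_under(traj, epi, config, base)
            expected = brute_force_deaths(traj, epi, config, base)
            for row in result.itertuples(index=False):
                exp = expected[(row.outcome, row.cause, row.year)]
                assert row.deaths == pytest.approx(exp, rel=1e-9, abs=1e-9)
            # attribution conservation per cause
            for (o, c) in causes:
                entries = [e for e in config if (e.outcome, e.cause) == (o, c)]
                if not entries:
                    continue
                cov_t = {iid: traj[iid][2020] for iid in iids}
                alloc = attribute_by_intervention(entries, base, cov_t,
                                                  epi.deaths[(o, c)])
                r0 = brute_force_deaths({i: {2016: base[i]} for i in iids},
                                        epi, config, base)
                joint = (epi.deaths[(o, c)]
                         - expected[(o, c, 2020)])
                assert sum(alloc.values()) == pytest.approx(joint, rel=1e-9,
                                                            abs=1e-9)


class TestCountryImpactProperties:
    def run(self, eff=0.5, cov0=0.2, cov1=0.6, d0=1000.0, live=1e5):
        config = [entry("a", eff=eff)]
        su = {"a": {2016: cov0, 2020: cov1}}
        cf = {"a": {2016: cov0, 2020: cov0}}
        epi = EpiProfile("X", 2016, live, live * 1.02,
                         {("neonatal", "sepsis"): d0,
                          ("stillbirth", "antepartum"): 100.0})
        return run_country_impact("X", su, cf, epi, config)

    def total_saved(self, res, year=2020):
        sub = res.lives_saved[res.lives_saved.year == year]
        return sub["lives_saved"].sum()

    def test_monotone_in_efficacy_and_coverage(self):
        base = self.total_saved(self.run())
        assert self.total_saved(self.run(eff=0.7)) >= base
        assert self.total_saved(self.run(cov1=0.9)) >= base
        assert base >= 0

    def test_scale_equivariance(self):
        """Doubling the death envelope doubles lives saved exactly."""
        a = self.total_saved(self.run(d0=1000.0))
        b = self.total_saved(self.run(d0=2000.0))
        # the stillbirth cause is untouched, so only the treated cause doubles
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_rate_decline_matches_death_decline(self):
        """With fixed denominators, percent declines in NMR equal percent
        declines in neonatal deaths."""
        res = self.run()
        rates = res.rates.set_index(["scenario_label", "year"])
        nmr0 = rates.loc[("counterfactual", 2016), "nmr"]
        nmr1 = rates.loc[("scale_up", 2020), "nmr"]
        deaths = res.deaths
        d0 = deaths[(deaths.scenario_label == "counterfactual")
                    & (deaths.year == 2016)
                    & (deaths.outcome == "neonatal")]["deaths"].sum()
        d1 = deaths[(deaths.scenario_label == "scale_up")
                    & (deaths.year == 2020)
                    & (deaths.outcome == "neonatal")]["deaths"].sum()
        assert (nmr0 - nmr1) / nmr0 == pytest.approx((d0 - d1) / d0, rel=1e-12)

    def test_attribution_sums_to_lives_saved(self):
        res = self.run()
        attr = res.attribution.groupby(["year", "outcome"])["deaths_averted"].sum()
        saved = res.lives_saved.set_index(["year", "outcome"])["lives_saved"]
        for key, v in saved.items():
            assert attr.get(key, 0.0) == pytest.approx(v, abs=1e-9)


def test_default_efficacy_matrix_is_valid(registry):
    """The shipped matrix references only registry interventions and known
    outcome/cause pairs, with effect sizes in [0, 1]."""
    entries = load_efficacy()
    iids = {d.intervention_id for d in registry}
    for e in entries:
        assert e.intervention_id in iids
        assert e.cause in CAUSES[e.outcome]
        assert 0.0 <= e.effect_size <= 1.0
    # every intervention contributes to at least one cause
    assert {e.intervention_id for e in entries} == iids
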