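# Methods

## Model overview

`careimpact` estimates the mortality impact of raising the quality of
facility-based maternal and newborn care to match current utilization. The
chain is: facility readiness × utilization → baseline effective coverage →
linear scale-up to a utilization cap → deterministic cause-specific
mortality model → lives saved and rate declines.

### Effective coverage from linked surveys

For an intervention with period *p* (antenatal, childbirth, postnatal),

  coverage = U_p · Σ_s share_s · readiness_s,

with U_p = ANC4+ for antenatal and facility-delivery (HFD) for
childbirth/postnatal interventions. Readiness per stratum is the
survey-weighted proportion of facilities possessing **all** required
components of the intervention's checklist (19 indicators; 8 antenatal, 7
childbirth, 4 postnatal; see `src/careimpact/data/indicator_registry.yaml`).
Assumptions:

* Readiness is a strict conjunction — a facility missing any single
  component is counted not ready. This is deliberately conservative; there
  is no partial-credit scoring.
* Components flagged SPA-only (staff-training items, chlorhexidine,
  observed thermal-care practice) are excluded from the requirement set
  when the facility survey is a SARA. If that leaves an indicator with no
  assessable components the intervention is flagged *absent* for that
  country rather than scored as trivially ready; absent interventions are
  later filled by the cross-country quantile proxy.
* Weights are normalized within stratum (design-based estimation); the
  stratum taxonomy is configurable, defaulting to
  {hospital, health_center, clinic} with shares taken from the household
  survey. With no stratum information a single national stratum works.
* A facility survey may be linked to a household survey only when their
  fieldwork midpoints are ≤ 2 years apart; multi-year fieldwork is encoded
  as a fractional midpoint year (2008–2009 → 2008.5).

### Baselines, proxies, and trajectories

2016 baselines are the linked estimates where available; other countries
receive the cross-country quantile (median centrally; 25th/75th
percentiles in sensitivity runs, computed by linear interpolation of order
statistics — the common default convention). Quantile substitution applies
only to proxied values; measured baselines are never replaced, because the
quartile bounds exist to probe the proxy assumption, not the data.

Scale-up coverage is linearly interpolated from the 2016 baseline to the
country's utilization cap in 2020, evaluated at integer calendar years.
When the baseline (typically a median proxy in a very-low-utilization
country) already exceeds the cap, the trajectory is held constant:
coverage is raised toward targets, never lowered. The counterfactual holds
coverage at baseline. Interventions outside the modeled set are implicitly
constant (they contribute zero impact by construction).

### Lives-saved engine

For each cause of death, interventions acting on it combine through the
residual mortality factor R(c) = Π_i (1 − E_i · AF_i · c_i), where E is
efficacy and AF the affected fraction (folded multiplicatively; no herd or
indirect effects). Observed 2016 envelopes are taken to already reflect
baseline coverage, so projected deaths use the residual *ratio*
D(y) = D(2016) · R(c(y)) / R(c(2016)). The multiplicative structure keeps
the joint reduction from several interventions below the sum of their
individual reductions, precluding double counting. A baseline residual of
zero with positive observed deaths is rejected as inconsistent input.

Per-intervention attribution computes the impact each intervention would
have alone and splits the joint total proportionally (allocations sum to
the joint total exactly; all zero when nothing moves). Proportional
allocation is a declared convention — the joint reduction has no unique
decomposition.

Rates use standard denominators: MMR per 100,000 live births, NMR per
1,000 live births, SBR per 1,000 total births (live + stillbirths). Birth
and death envelopes are held constant over 2016–2020; no demographic
projection. Impact is reported per year, with 2020 the endline snapshot.

### Sensitivity bounds

The q25/median/q75 runs vary *starting* coverage in proxied countries. A
higher start leaves less headroom below the fixed cap, so the q75 run
supplies the low end of the lives-saved range and the q25 run the high
end. The ordering is verified at aggregation time and flagged (never
silently reordered) if crossed — a crossing would indicate a cap-rule
interaction.

"Impact overall" pools the three outcomes by raw count (stillbirths
dominate numerically); per-outcome period shares are also emitted. Percent
rate declines are summarized across countries by median and quartiles
(population-weighted means available via the summary's `mean` entry).

## Efficacy configuration

The packaged matrix (`src/careimpact/data/efficacy_default.csv`) is an
illustrative default: it respects the standard intervention → outcome/cause
topology (e.g., neonatal resuscitation → intrapartum-related neonatal
deaths; AMTSL → maternal hemorrhage; MgSO4 → hypertensive disorders and
stillbirth) but its efficacy and affected-fraction values are configuration
placeholders, **not** authoritative effectiveness estimates. Analyses of
real data should supply their own matrix (CSV columns: intervention_id,
outcome, cause, efficacy, affected_fraction; each entry at most once, with
efficacy × affected_fraction in [0, 1]).

## Synthetic-data generator

The generator emulates the study conditions end to end: 81 countries (17
linked, 64 unlinked), facility surveys alternating SPA and SARA with
fieldwork 2007–2015 and household surveys within ±2 years, utilization
drawn from beta distributions centred near the low observed levels typical
of high-burden settings (ANC4+ mean ≈ 0.60, clipped to [0.06, 0.96]; HFD
mean ≈ 0.66, clipped to [0.09, 0.99]), Dirichlet stratum shares, and
epidemiological envelopes with MMR ~ U(100, 800), NMR ~ U(15, 45),
SBR ~ U(10, 30) on their usual scales and Dirichlet cause structures with
roughly realistic means.

Component availability uses a **binding-component scheme**: each
intervention carries one scarce component (its rarest checklist item, with
base availability uniform on [0.35, 0.95], degraded by stratum: hospitals
×1.0, health centers ×0.85, clinics ×0.70); shared guideline/training
components are otherwise universally present. Per-component Bernoulli
probabilities are solved so every intervention's all-components-present
probability equals its target readiness exactly. One structural constraint
follows from the checklists themselves: the induction-of-labor requirement
set is a subset of AMTSL's, so readiness(AMTSL) ≤ readiness(induction)
necessarily; the solver rejects infeasible targets with an explicit error,
and the forward sampler always produces feasible ones.
`GroundTruth.expected_readiness` exposes the exact conjunction probability
per intervention × stratum × survey type — under SARA, SPA-only components
drop out, so e.g. AMTSL's expected readiness equals induction's and the
cord-care/thermal-care/KMC indicators reduce to the IMPAC-guidelines
probability. Recovery tests compare estimates against these closed forms.

What the generator does **not** emulate: real recode file layouts, cluster
sampling and nonresponse, within-intervention component correlation beyond
the binding-component structure, and between-country correlation of
readiness with utilization. Passing tests therefore demonstrate that the
estimators and the projection arithmetic are correct under known ground
truth, not that any particular real-world coverage level is reproduced.

## Numerical choices

* Conjunction/readiness estimates are exact weighted proportions; no
  smoothing.
* Quantiles: linear interpolation of order statistics.
* Floating-point guards: effective coverage clipped to [0, 1] against
  rounding overshoot; conservation of attribution checked at 1e-9 relative;
  trajectory endpoints exact to 1e-12.
* Largest-remainder allocation of facilities to strata, with every
  nonzero-share stratum guaranteed at least one facility when the sample
  size allows, so stratum readiness is always estimable.
* All randomness flows through explicit integer seeds (no global RNG);
  repeated runs are byte-identical.

## Problem sizes

The default study set is 81 countries with 400 facilities per linked
country (the acceptance script's setting); the test suite uses 200–5,000
facilities depending on the precision the check needs (5,000 for
3-standard-error recovery of effective coverage; ≤ 20 for brute-force
enumeration oracles). These sizes are the package's own choices for a
desk-scale synthetic study.

## Limitations

* Readiness is structural only; observed processes of care, provider
  competence, and actual receipt of interventions are not modeled, so
  effective coverage here is an upper-bound-style approximation of quality.
* The median-proxy assumption treats linked countries as representative of
  unlinked ones; the quartile bounds probe, but cannot eliminate, that
  assumption.
* Constant envelopes ignore demographic change over the projection window
  and any feedback from improved quality to care-seeking demand.
* The per-intervention attribution is a convention; only the joint total
  is model-determined.
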