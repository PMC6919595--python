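# careimpact

Effective-coverage estimation and deterministic lives-saved projection for
maternal and newborn health.

## The problem

In many low- and middle-income countries a growing share of pregnant women
reach antenatal care and deliver in health facilities, yet mortality stays
high because the facilities they reach often lack the drugs, equipment,
guidelines, or trained staff needed to actually deliver life-saving care.
*Effective coverage* — the fraction of the population in need that receives
an intervention at adequate quality — is therefore much lower than
utilization alone suggests.

`careimpact` is a pipeline for quantifying what closing that quality gap
would be worth. It is aimed at epidemiologists and health-systems modellers
who work with facility-readiness surveys (SPA/SARA-style component
checklists) and household surveys (DHS/MICS-style utilization indicators).
The pipeline:

1. **Links** a facility survey to a household survey (fieldwork at most
   ±2 years apart) to estimate baseline effective coverage of 19 antenatal,
   childbirth, and postnatal interventions:

   `coverage = U · Σ_s share_s · readiness_s`

   where `U` is the utilization cap for the intervention's period (ANC4+
   for antenatal care, facility delivery for childbirth/postnatal care),
   `share_s` the share of care contacts in facility stratum `s`, and
   `readiness_s` the survey-weighted proportion of facilities in stratum
   `s` with *every* structural component the intervention requires (strict
   conjunction, no partial credit).
2. **Imputes** baselines for countries without a linked survey pair using
   the cross-country sample median (25th/75th percentiles as sensitivity
   bounds).
3. **Projects** coverage linearly from the 2016 baseline to the
   country-specific utilization cap in 2020; coverage is never decreased,
   and a counterfactual freezes coverage at baseline.
4. **Models impact** with a deterministic cause-specific mortality model:
   for each cause, interventions combine through a residual factor
   `R(c) = Π_i (1 − E_i·AF_i·c_i)` (efficacy × affected fraction ×
   coverage), and deaths scale by the residual ratio
   `D(y) = D(2016)·R(c(y))/R(c(2016))` — a structure that precludes
   double counting. Lives saved = counterfactual deaths − scale-up deaths;
   per-intervention attribution splits the joint total proportionally to
   single-intervention impacts.
5. **Reports** global totals with sensitivity ranges, percent declines in
   the maternal mortality ratio (MMR, per 100,000 live births), neonatal
   mortality rate (NMR, per 1,000 live births) and stillbirth rate (SBR,
   per 1,000 total births), and the share of impact by care period.

A synthetic-data generator produces all inputs with known ground truth, so
the entire pipeline is testable without access-restricted survey microdata.

## Worked example

```bash
cat > config.yaml <<'EOF'
synthetic:
  n_linked: 17
  n_unlinked: 64
  n_facilities: 400
seed: 42
bound: all
out_dir: example_out
EOF
careimpact run --config config.yaml
```

prints (the numbers come from the synthetic 81-country set generated with
seed 42 and the packaged illustrative efficacy matrix):

```
Global impact summary, endline year 2020
================================================

Lives saved / stillbirths prevented:
  maternal lives saved      : 14,918 (range, 12,574-17,756)
  neonatal lives saved      : 145,689 (range, 119,519-174,270)
  stillbirths prevented     : 70,669 (range, 54,881-83,263)

Median percent decline in mortality rates (IQR across countries):
  MMR: 9.2% (6.8% to 11.6%)
  NMR: 12.3% (7.1% to 15.5%)
  SBR: 8.5% (6.0% to 10.9%)

Share of total impact by care period:
  antenatal   : 16.1%
  childbirth  : 53.8%
  postnatal   : 30.1%
    maternal  : antenatal 28%, childbirth 72%, postnatal 0%
    neonatal  : antenatal 7%, childbirth 45%, postnatal 48%
    stillbirth: antenatal 32%, childbirth 68%, postnatal 0%
```

Reading the output: had quality of care been raised so that everyone
already seeking care received these 19 interventions, the model projects
14,918 maternal and 145,689 neonatal deaths and 70,669 stillbirths averted
in 2020 across the 81 synthetic countries, relative to no change in
quality. The range in parentheses comes from re-running the pipeline with
25th/75th-percentile baseline proxies in unlinked countries (a higher
starting baseline leaves less headroom below the fixed utilization cap,
hence fewer lives saved). Interventions at childbirth dominate the total.

`example_out/` also contains the stage outputs: linked effective-coverage
estimates, coverage trajectories, deaths by cause under both scenarios,
per-intervention lives saved, per-bound summaries, and a provenance log.

Other subcommands (`simulate`, `link`, `project`, `impact`, `report`) run
individual stages; `careimpact simulate` writes the synthetic dataset CSVs
plus the ground-truth parameters for inspection.

## Scope

The package models quality improvement at *current* utilization only: no
demand growth, no demographic projection, no post-neonatal child mortality,
and no process-of-care measurement. The shipped efficacy matrix is an
illustrative configuration respecting the standard intervention → cause
topology, not a set of authoritative effectiveness estimates; substitute
your own via `efficacy_path`. See `docs/methods.md` for the model details
and limitations.
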