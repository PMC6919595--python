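# Readiness indicator registry: the minimum set of structural inputs assumed
# required for adequate delivery of each of the 19 maternal/newborn health
# interventions, as assessed in SPA/SARA facility surveys. A facility is
# "ready" for an intervention iff every listed component is available.
# Components flagged spa_only are assessed only in SPA surveys and are dropped
# from the requirement set when evaluating a SARA survey.
#
# Component code vocabulary (one code per checklist line item):
#   tt_vaccine            valid unexpired tetanus toxoid vaccine
#   anc_staff_trained     >=1 staff trained in at least one aspect of ANC
#   anc_guidelines        ANC guidelines reported available
#   sp_tablets            valid unexpired sulphadoxine/pyrimethamine
#   syphilis_test         valid syphilis test (RDT, RPR, or VDRL)
#   injectable_penicillin valid unexpired benzathine or procaine penicillin
#   iron_tablets          valid unexpired iron or iron+folic acid tablets
#   urine_protein_dipstick valid dipstick for urine protein
#   bp_apparatus          functioning blood pressure apparatus
#   antihypertensive      valid unexpired amlodipine/nifedipine/methyldopa
#   glucometer_strips     glucometer AND test strips
#   urine_glucose_dipstick valid dipstick for urine glucose
#   malaria_diagnostics   RDT kit, or smear microscopy with slides and stain
#   act_unit              valid unexpired artemisinin-based combination therapy
#   mgso4_anc             valid unexpired magnesium sulfate (ANC service)
#   impac_guidelines      IMPAC guidelines observed available
#   infection_prev_guidelines guidelines on standard precautions
#   hand_hygiene          soap+running water, or gloves, or alcohol hand rub
#   sterilizer            functional dry heat sterilizer or autoclave
#   partograph            blank partographs
#   delivery_pack         delivery pack or full equivalent instrument set
#   delivery_bed          delivery bed
#   spotlight             functional spotlight source or flashlight
#   staff_nn_resusc       staff trained for neonatal resuscitation, past 2 yrs
#   newborn_bag_mask      functional newborn bag and mask
#   azithromycin          valid unexpired azithromycin
#   injectable_mgso4      valid injectable magnesium sulfate where stocked
#   staff_amtsl           staff trained in AMTSL, past 2 yrs
#   uterotonic            valid injectable uterotonic or oral misoprostol
#   chlorhexidine         valid unexpired chlorhexidine
#   thermal_practice      routinely observed drying/wrapping or skin-to-skin
#   staff_kmc             staff trained in Kangaroo Mother Care, past 2 yrs
#   injectable_antibiotics valid procaine benzylpenicillin, or gentamicin and
#                         ceftriaxone

interventions:
  # --- antenatal care (8) ---
  - id: tetanus_toxoid
    label: Tetanus toxoid vaccination
    period: antenatal
    components: [tt_vaccine, anc_staff_trained, anc_guidelines]
  - id: iptp_malaria
    label: Intermittent preventive treatment of malaria in pregnancy
    period: antenatal
    components: [sp_tablets, anc_staff_trained, anc_guidelines]
  - id: syphilis_detection_treatment
    label: Syphilis detection and treatment
    period: antenatal
    components: [syphilis_test, injectable_penicillin, anc_staff_trained, anc_guidelines]
  - id: iron_supplementation
    label: Iron supplementation in pregnancy
    period: antenatal
    components: [iron_tablets, anc_staff_trained, anc_guidelines]
  - id: hypertensive_disorder_mgmt
    label: Hypertensive disorder case management
    period: antenatal
    components: [urine_protein_dipstick, bp_apparatus, antihypertensive, anc_staff_trained, anc_guidelines]
  - id: diabetes_mgmt
    label: Diabetes case management
    period: antenatal
    components: [glucometer_strips, urine_glucose_dipstick, anc_staff_trained, anc_guidelines]
  - id: malaria_case_mgmt
    label: Malaria case management
    period: antenatal
    components: [malaria_diagnostics, act_unit, anc_staff_trained, anc_guidelines]
  - id: mgso4_preeclampsia
    label: MgSO4 management of pre-eclampsia
    period: antenatal
    components: [mgso4_anc, anc_staff_trained, anc_guidelines]

  # --- childbirth care (7) ---
  - id: clean_birth_practices
    label: Clean birth practices
    period: childbirth
    components: [impac_guidelines, infection_prev_guidelines, hand_hygiene, sterilizer]
  - id: labor_delivery_mgmt
    label: Labor and delivery management
    period: childbirth
    components: [partograph, delivery_pack, delivery_bed, spotlight, impac_guidelines]
  - id: neonatal_resuscitation
    label: Neonatal resuscitation
    period: childbirth
    components: [staff_nn_resusc, newborn_bag_mask, impac_guidelines]
    spa_only: [staff_nn_resusc]
  - id: antibiotics_pprom
    label: Antibiotics for pPRoM
    period: childbirth
    components: [azithromycin, impac_guidelines]
  - id: mgso4_eclampsia
    label: Management of eclampsia with MgSO4
    period: childbirth
    components: [injectable_mgso4, impac_guidelines]
  - id: amtsl
    label: Active management of the third stage of labor
    period: childbirth
    components: [staff_amtsl, uterotonic, impac_guidelines]
    spa_only: [staff_amtsl]
  - id: induction_41wk
    label: Induction of labor for pregnancies lasting 41+ weeks
    period: childbirth
    components: [uterotonic, impac_guidelines]

  # --- postnatal care (4) ---
  - id: hygienic_cord_care
    label: Hygienic cord care
    period: postnatal
    components: [chlorhexidine, impac_guidelines]
    spa_only: [chlorhexidine]
  - id: thermal_care
    label: Thermal care for premature babies
    period: postnatal
    components: [thermal_practice, impac_guidelines]
    spa_only: [thermal_practice]
  - id: kangaroo_mother_care
    label: Kangaroo Mother Care for premature babies
    period: postnatal
    components: [staff_kmc, impac_guidelines]
    spa_only: [staff_kmc]
  - id: neonatal_sepsis_antibiotics
    label: Case management of neonatal sepsis/pneumonia with injectable antibiotics
    period: postnatal
    components: [injectable_antibiotics, impac_guidelines]
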