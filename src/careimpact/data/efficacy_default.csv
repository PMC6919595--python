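intervention_id,outcome,cause,efficacy,affected_fraction
tetanus_toxoid,neonatal,tetanus,0.94,0.90
iptp_malaria,maternal,other_maternal,0.25,0.15
iptp_malaria,stillbirth,antepartum,0.20,0.20
syphilis_detection_treatment,stillbirth,antepartum,0.80,0.08
syphilis_detection_treatment,neonatal,prematurity,0.50,0.05
iron_supplementation,maternal,other_maternal,0.20,0.20
hypertensive_disorder_mgmt,maternal,hypertensive_disorders,0.35,0.55
hypertensive_disorder_mgmt,stillbirth,antepartum,0.20,0.15
diabetes_mgmt,stillbirth,antepartum,0.30,0.05
diabetes_mgmt,neonatal,other_neonatal,0.20,0.05
malaria_case_mgmt,maternal,other_maternal,0.30,0.15
malaria_case_mgmt,stillbirth,antepartum,0.25,0.10
mgso4_preeclampsia,maternal,hypertensive_disorders,0.40,0.40
mgso4_preeclampsia,stillbirth,antepartum,0.15,0.10
clean_birth_practices,maternal,sepsis,0.25,0.60
clean_birth_practices,neonatal,sepsis,0.25,0.50
clean_birth_practices,neonatal,tetanus,0.30,0.40
labor_delivery_mgmt,maternal,obstructed_labor,0.50,0.60
labor_delivery_mgmt,neonatal,intrapartum_related,0.30,0.50
labor_delivery_mgmt,stillbirth,intrapartum,0.45,0.70
neonatal_resuscitation,neonatal,intrapartum_related,0.40,0.80
antibiotics_pprom,neonatal,prematurity,0.12,0.30
antibiotics_pprom,neonatal,sepsis,0.08,0.20
mgso4_eclampsia,maternal,hypertensive_disorders,0.50,0.60
mgso4_eclampsia,stillbirth,intrapartum,0.15,0.20
amtsl,maternal,hemorrhage,0.50,0.70
induction_41wk,stillbirth,intrapartum,0.30,0.10
hygienic_cord_care,neonatal,sepsis,0.25,0.40
hygienic_cord_care,neonatal,tetanus,0.30,0.30
thermal_care,neonatal,prematurity,0.20,0.40
kangaroo_mother_care,neonatal,prematurity,0.35,0.50
neonatal_sepsis_antibiotics,neonatal,sepsis,0.65,0.80
neonatal_sepsis_antibiotics,neonatal,pneumonia,0.60,0.70
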