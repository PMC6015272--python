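service_type,unit_cost,source
gp_surgery,38,PSSRU 2014
gp_home_visit,62,PSSRU 2014
gp_telephone,23,PSSRU 2014
nurse_surgery,11,PSSRU 2014
nurse_home_visit,18,PSSRU 2014
walk_in_clinic,56,PSSRU 2014
ooh_telephone,36,OOH GP services / PSSRU 2014
ooh_home_visit,117,OOH GP services / PSSRU 2014
ooh_surgery,86,OOH GP services / PSSRU 2014
a_and_e,167,Reference Costs 2013-14
podiatrist,44,Reference Costs 2013-14
optometry,97,Reference Costs 2013-14
physiotherapy,46,Reference Costs 2013-14
counselling_primary,46,PSSRU 2014
counselling_community,138,Reference Costs 2013-14
clinical_test,2,Reference Costs 2013-14
outpatient,111,Reference Costs 2013-14
day_case,698,Reference Costs 2013-14
inpatient,1891,Reference Costs 2013-14
district_nurse_home,46,Reference Costs 2013-14 / PSSRU 2014
district_nurse_clinic,37,Reference Costs 2013-14
social_worker,55,PSSRU 2014
occupational_therapy,64,Reference Costs 2013-14
dietician,80,Reference Costs 2013-14
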