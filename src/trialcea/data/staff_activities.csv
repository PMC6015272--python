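activity,hours_per_period,periods_per_year,rate,printed_cost
emails_newsletters_sms,7.5,26,34,6675
librarian_review,1,52,30,1560
patient_reps_feedback_on_review,1,26,18,468
forum_monitoring_patient_reps,1,26,18,468
forum_monitoring_staff,1,26,34,890
clinical_team_website_interaction,1,5,121,605
patient_reps_review_clinical_feedback,0.5,5,18,45
content_update_staff,2,26,34,1780
content_update_clinical_team,2,26,121,6292
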