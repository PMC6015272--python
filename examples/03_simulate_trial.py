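"""Generate a synthetic two-arm trial and inspect its structure.

Defaults emulate the published trial: 374 participants over 21 centres,
permuted-block randomization, arm-level outcome means calibrated to the
published summary table, and questionnaire nonresponse at the published
completion rates.
"""

from trialcea import pipeline, synthetic

cfg = synthetic.TrialConfig(seed=7)
df, meta = synthetic.generate_trial(cfg)
print(f"{len(df)} participants over {df['center'].nunique()} centres; "
      f"arm sizes {df['arm'].value_counts().to_dict()}")

missing = synthetic.impose_missingness(df, cfg)
table = pipeline.prepare_analysis_table(missing)

print("\narm-level means (observed data):")
print(table.groupby("arm")[["u_0", "u_3", "u_12", "paid_0", "paid_12"]]
      .mean().round(3).to_string())

comp12 = 1 - table["u_12_raw"].isna().groupby(table["arm"]).mean()
print("\n12-month questionnaire completion:")
print(comp12.round(2).to_string())
print("\nUtility means track the published 0.79/0.77 baselines and the "
      "~70% completion the analysis must cope with.")
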