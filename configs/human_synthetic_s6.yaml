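# SYNTHETIC reconstruction of the human simulation parameter table.
# The original supplementary table is not part of this repository; printed
# main-text constants are used where available (V1, V2, renal clearance,
# transport rate from the infusion-trial fit) and the remaining entries
# (per-capsule production, capsule decay, thresholds) are reconstructed
# once from main-text constraints: production at the in-vitro estimate,
# decay shared with the mouse scenario, effector threshold placed so a
# 5000-capsule dose yields the reported ~13-day therapeutic window.
k_prod_pg_per_day_per_capsule: 1.0e4
k_trans_per_day: 0.7
k_clr_ml_per_day: 1.68e5
lambda_per_day: 0.45
V1_ml: 20.0
V2_ml: 5320.0
effector_threshold_pg_per_ml: 21000.0
toxicity_threshold_pg_per_ml: 1.0e5
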