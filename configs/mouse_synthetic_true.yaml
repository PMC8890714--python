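# SYNTHETIC generating parameters for the mouse single-dose PK scenario
# (200 capsules, IP + blood sampling over 30 days).  Production and decay
# lie inside the literature fitting bounds; the clearance corresponds to
# 0.5 ml/min, which reproduces the measurable ng/ml-scale blood
# concentrations seen in mouse PK data.
k_prod_pg_per_day_per_capsule: 1.0e4
k_trans_per_day: 0.6
k_clr_ml_per_day: 720.0
lambda_per_day: 0.45
V1_ml: 1.0
V2_ml: 1.2
effector_threshold_pg_per_ml: 1000.0
toxicity_threshold_pg_per_ml: 1.0e4
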