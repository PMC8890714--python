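# SYNTHETIC reconstruction of the NHP simulation parameter table, for a
# 4 kg animal: V2 = 65*m ml, V1 from the human V1:V2 ratio, clearance from
# linear mass scaling (7200 ml/day at 2 kg).  Transport rate is the human
# infusion-trial estimate; the capsule decay rate is ~50% faster than the
# mouse value, consistent with the faster kinetics observed in primates,
# and places the 1795-capsule therapeutic window at ~13 days.
k_prod_pg_per_day_per_capsule: 1.0e4
k_trans_per_day: 0.7
k_clr_ml_per_day: 14400.0
lambda_per_day: 0.70
V1_ml: 0.9774436090225564
V2_ml: 260.0
effector_threshold_pg_per_ml: 21000.0
toxicity_threshold_pg_per_ml: 1.0e5
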