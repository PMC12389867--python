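# Printed group-mean rows of the reference cohort table, with the significance
# asterisks attached to each column (a flag marks a reported SZ-vs-CNT group
# difference at alpha = 0.05). known_discrepancy names the group (if any) whose
# printed mean differs from the mean of the printed per-subject values by more
# than 0.005 (rounding artifacts of the source table; see docs/methods.md).
measure,sz_mean,cnt_mean,significant,known_discrepancy
co_5_2,0.87,0.98,1,
co_5_4,0.85,0.96,1,
co_5_8,0.37,0.39,0,
co_10_2,0.95,1.00,0,
co_10_4,0.95,1.00,0,SZ
co_10_8,0.94,0.99,1,
co_15_2,0.97,1.00,0,
co_15_4,0.97,1.00,0,
co_15_8,0.97,1.00,0,SZ
dtheta_sample,0.66,0.56,1,SZ
dtheta_regr,0.31,0.09,1,
area_250,0.09,0.04,0,
area_500,0.15,0.06,0,
area_750,0.17,0.08,0,
area_1000,0.10,0.06,0,CNT
area_1500,0.21,0.13,0,
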