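# Per-subject smooth-pursuit index values for the reference pilot cohort
# (9 patients with schizophrenia, SZ; 9 healthy controls, CNT), transcribed
# from the published per-subject table of the original study.
# co_<r1>_<r2>: spatiotemporal colocality at target-ball radius r1 mm and
#   gaze-ball radius r2 mm (dimensionless, [0, 1]).
# dtheta_sample: 1 - mean resultant length of per-step angle differences.
# dtheta_regr: mean segment-wise regression-line orientation difference (rad).
# area_<ms>: mean polygon area in normalized units at the window length in ms
#   (250 ms = 15 samples at 60 Hz, ..., 1500 ms = 90 samples).
subject,group,co_5_2,co_5_4,co_5_8,co_10_2,co_10_4,co_10_8,co_15_2,co_15_4,co_15_8,dtheta_sample,dtheta_regr,area_250,area_500,area_750,area_1000,area_1500
SZ_1,SZ,0.98,0.95,0.39,1.00,1.00,0.99,1.00,1.00,1.00,0.61,0.49,0.00,0.00,0.01,0.00,0.13
SZ_2,SZ,0.92,0.88,0.38,0.99,0.99,0.97,1.00,1.00,1.00,0.57,0.70,0.01,0.08,0.17,0.13,0.43
SZ_3,SZ,0.96,0.94,0.39,0.99,0.99,0.98,0.99,1.00,1.00,0.68,0.11,0.20,0.20,0.16,0.03,0.30
SZ_4,SZ,0.89,0.87,0.39,1.00,1.00,0.96,1.00,1.00,1.00,0.60,0.19,0.01,0.11,0.04,0.02,0.10
SZ_5,SZ,0.89,0.88,0.39,0.95,0.96,0.96,0.98,0.98,0.99,0.62,0.16,0.06,0.09,0.22,0.35,0.38
SZ_6,SZ,0.35,0.37,0.23,0.61,0.66,0.64,0.73,0.78,0.79,0.89,0.33,0.20,0.49,0.49,0.19,0.19
SZ_7,SZ,0.96,0.91,0.38,1.00,1.00,0.98,1.00,1.00,1.00,0.61,0.37,0.01,0.03,0.06,0.04,0.08
SZ_8,SZ,0.98,0.97,0.39,0.99,1.00,0.99,1.00,1.00,1.00,0.58,0.25,0.00,0.03,0.07,0.02,0.13
SZ_9,SZ,0.93,0.90,0.38,1.00,1.00,0.98,1.00,1.00,1.00,0.62,0.20,0.33,0.34,0.34,0.13,0.19
CNT_1,CNT,0.99,0.97,0.39,1.00,1.00,0.99,1.00,1.00,1.00,0.43,0.02,0.03,0.09,0.10,0.04,0.04
CNT_2,CNT,0.98,0.96,0.39,1.00,1.00,0.99,1.00,1.00,1.00,0.49,0.07,0.00,0.02,0.06,0.00,0.09
CNT_3,CNT,1.00,0.97,0.39,1.00,1.00,1.00,1.00,1.00,1.00,0.51,0.15,0.01,0.01,0.02,0.02,0.14
CNT_4,CNT,0.98,0.97,0.39,1.00,1.00,0.99,1.00,1.00,1.00,0.55,0.08,0.00,0.01,0.06,0.07,0.12
CNT_5,CNT,0.96,0.93,0.39,1.00,1.00,0.98,1.00,1.00,1.00,0.55,0.10,0.04,0.06,0.08,0.06,0.06
CNT_6,CNT,0.98,0.95,0.39,1.00,1.00,0.99,1.00,1.00,1.00,0.64,0.10,0.27,0.33,0.31,0.24,0.40
CNT_7,CNT,0.99,0.96,0.39,1.00,1.00,0.99,1.00,1.00,1.00,0.68,0.10,0.00,0.00,0.00,0.01,0.14
CNT_8,CNT,0.98,0.96,0.39,1.00,1.00,0.99,1.00,1.00,1.00,0.49,0.08,0.01,0.02,0.02,0.02,0.16
CNT_9,CNT,0.99,0.98,0.39,1.00,1.00,1.00,1.00,1.00,1.00,0.71,0.14,0.01,0.04,0.06,0.02,0.05
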