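target,complex_id,rmsd,rog,rmsf,sasa,n_hbond
PTP1B,PTP1B-Q37DG,1.48 ± 0.11,19.49 ± 0.08,1.06 ± 0.49,12930.30 ± 270.93,156.57 ± 8.07
PTP1B,PTP1B-beta-cadinene,1.50 ± 0.34,19.58 ± 0.13,1.20 ± 0.56,13227.25 ± 325.12,152.09 ± 8.48
PTP1B,PTP1B-Q7G,1.45 ± 0.12,19.45 ± 0.14,1.04 ± 0.53,12898.03 ± 343.23,153.45 ± 8.36
PTP1B,PTP1B-cadinenol,1.46 ± 0.24,19.41 ± 0.06,1.15 ± 0.50,12933.48 ± 338.33,151.61 ± 8.82
PTP1B,PTP1B-5IMME,1.44 ± 0.24,19.42 ± 0.11,1.10 ± 0.56,13157.67 ± 402.71,152.92 ± 8.02
PTP1B,PTP1B-ursolic-acid,1.43 ± 0.29,19.50 ± 0.09,1.03 ± 0.55,13078.24 ± 353.52,152.94 ± 8.18
PTP1B,PTP1B-apo,1.41 ± 0.17,19.35 ± 0.07,1.08 ± 0.54,13047.79 ± 356.31,151.22 ± 8.58
DPP4,DPP4-rutin,1.84 ± 0.33,26.90 ± 0.08,1.05 ± 0.51,29503.69 ± 401.15,380.35 ± 12.7
DPP4,DPP4-Q37DG,1.67 ± 0.19,26.83 ± 0.09,1.15 ± 0.47,28926.93 ± 694.05,386.70 ± 13.5
DPP4,DPP4-Q7G,2.52 ± 0.33,27.00 ± 0.09,1.16 ± 0.50,29870.35 ± 444.01,380.30 ± 12.3
DPP4,DPP4-piperitol,1.98 ± 0.57,27.10 ± 0.17,1.17 ± 0.49,30536.28 ± 546.52,373.55 ± 12.8
DPP4,DPP4-diosmetin,2.41 ± 0.20,27.16 ± 0.13,1.17 ± 0.47,30007.78 ± 403.86,374.01 ± 12.3
DPP4,DPP4-sitagliptin,1.71 ± 0.17,27.04 ± 0.08,1.14 ± 0.45,29943.96 ± 416.13,381.91 ± 13.6
DPP4,DPP4-apo,1.81 ± 0.22,27.00 ± 0.09,1.15 ± 0.52,29805.72 ± 383.89,378.13 ± 12.3
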