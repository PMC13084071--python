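target,complex_id,e_vdw,e_elec,e_gb,e_surf,g_gas,g_solv,g_bind
PTP1B,PTP1B-Q37DG,-44.05 ± 7.74,-94.84 ± 23.2,93.93 ± 14.38,-7.22 ± 0.50,-138.9 ± 19.8,86.71 ± 14.2,-52.19 ± 8.31
PTP1B,PTP1B-beta-cadinene,-13.82 ± 7.87,-0.44 ± 0.95,4.96 ± 2.41,-1.84 ± 1.03,-14.27 ± 8.04,3.12 ± 1.55,-11.14 ± 6.94
PTP1B,PTP1B-Q7G,-39.39 ± 6.84,-55.55 ± 17.3,61.92 ± 11.06,-5.39 ± 0.62,-94.95 ± 15.4,56.32 ± 11.1,-38.63 ± 7.78
PTP1B,PTP1B-cadinenol,-12.21 ± 6.78,-2.59 ± 3.80,7.49 ± 4.59,-1.62 ± 0.90,-14.80 ± 8.80,5.86 ± 3.94,-8.94 ± 5.76
PTP1B,PTP1B-5IMME,-16.76 ± 6.97,-5.93 ± 4.10,10.13 ± 4.67,-2.32 ± 0.98,-22.70 ± 9.87,7.76 ± 3.90,-14.93 ± 6.78
PTP1B,PTP1B-ursolic-acid,-31.48 ± 4.76,-5.38 ± 7.66,15.93 ± 5.49,-4.00 ± 0.57,-36.87 ± 7.75,11.92 ± 5.39,-24.95 ± 4.39
DPP4,DPP4-rutin,-38.25 ± 5.19,-87.7 ± 20.3,82.42 ± 15.50,-5.82 ± 0.37,-125.9 ± 18.7,76.59 ± 15.4,-49.36 ± 6.55
DPP4,DPP4-Q37DG,-44.41 ± 5.94,-103.3 ± 23.3,96.54 ± 12.34,-6.98 ± 0.57,-147.7 ± 22.9,89.55 ± 12.0,-58.23 ± 14.1
DPP4,DPP4-Q7G,-28.73 ± 4.89,-81.53 ± 18.7,74.81 ± 10.84,-4.50 ± 0.36,-110.9 ± 16.6,70.31 ± 10.7,-39.95 ± 7.58
DPP4,DPP4-piperitol,-26.55 ± 4.09,-22.12 ± 13.4,31.90 ± 7.93,-3.37 ± 0.46,-48.68 ± 13.2,28.60 ± 7.75,-20.07 ± 6.75
DPP4,DPP4-diosmetin,-30.66 ± 4.98,-24.55 ± 7.96,35.89 ± 5.99,-3.77 ± 0.39,-55.22 ± 8.49,32.12 ± 5.89,-23.11 ± 4.53
DPP4,DPP4-sitagliptin,-26.17 ± 5.93,-315.3 ± 43.2,321.49 ± 39,-4.02 ± 0.57,-341.5 ± 39,317.4 ± 38.5,-24.10 ± 6.91
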