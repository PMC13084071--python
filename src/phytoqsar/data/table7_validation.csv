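section,parameter,ptp1b,dpp4,threshold,comment
internal,see,0.219,0.202,,
internal,r2,0.880,0.952,>0.6,Passed
internal,r2_adj,0.877,0.948,>0.6,Passed
internal,press,15.409,206.871,,
loo,q2_loo,0.873,0.942,>0.6,Passed
loo,avg_rm2_loo,0.829,0.919,>0.6,Passed
loo,delta_rm2_loo,0.082,0.035,,
external,r2_ext,0.867,0.949,>0.6,Passed
external,r0_2,0.862,0.940,>0.6,Passed
external,r0_prime_2,0.814,0.923,>0.6,Passed
external,rmsep,0.206,0.257,,
external,q2_f1,0.863,0.942,>0.6,Passed
external,q2_f2,0.862,0.938,>0.6,Passed
external_scaled,avg_rm2_test,0.769,0.818,>0.6,Passed
external_scaled,delta_rm2_test,0.100,0.057,,
error_based,mae_95,0.156,0.198,,
error_based,sd_95,0.102,0.112,,
error_based,mae_verdict,GOOD,GOOD,,
golbraikh_tropsha,q2,0.873,0.942,>0.5,Passed
golbraikh_tropsha,r2,0.867,0.949,>0.6,Passed
golbraikh_tropsha,abs_r0_diff,0.047,0.017,<0.3,Passed
golbraikh_tropsha,k,1.001,0.992,0.85 < k < 1.15,Passed
golbraikh_tropsha,ratio_r0,0.006,0.001,<0.1,Passed
golbraikh_tropsha,k_prime,0.998,1.006,0.85 < k' < 1.15,Passed
golbraikh_tropsha,ratio_r0_prime,0.061,0.028,<0.1,Passed
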