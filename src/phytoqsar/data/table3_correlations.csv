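target,parameter,g_bind,rmsd,rog,rmsf,sasa,n_hbond
PTP1B,g_bind,1.000,,,,,
PTP1B,rmsd,-0.036,1.000,,,,
PTP1B,rog,-0.059,0.575,1.000,,,
PTP1B,rmsf,0.830,0.444,0.415,1.000,,
PTP1B,sasa,0.594,0.188,0.508,0.659,1.000,
PTP1B,n_hbond,-0.923,0.187,0.083,-0.698,-0.406,1.000
DPP4,g_bind,1.000,,,,,
DPP4,rmsd,0.311,1.000,,,,
DPP4,rog,0.952,0.549,1.000,,,
DPP4,rmsf,0.519,0.373,0.538,1.000,,
DPP4,sasa,0.918,0.411,0.888,0.409,1.000,
DPP4,n_hbond,-0.789,-0.545,-0.885,-0.303,-0.864,1.000
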