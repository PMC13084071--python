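target,compound,g_bind,homo,lumo,delta_e,ip,ea,eta,xi,chi,mu,omega
PTP1B,Q37DG,-52.19,-5.80,-1.66,4.14,5.8,1.66,2.07,0.48,3.73,-3.73,3.36
PTP1B,beta-cadinene,-11.14,-6.09,0.88,6.97,6.09,-0.88,3.49,0.29,2.61,-2.61,0.97
PTP1B,Q7G,-38.63,-5.68,-1.55,4.13,5.68,1.55,2.07,0.48,3.62,-3.62,3.16
PTP1B,cadinenol,-8.94,-6.16,0.80,6.96,6.16,-0.80,3.48,0.29,2.68,-2.68,1.03
PTP1B,5IMME,-14.93,-6.22,-0.91,5.31,6.22,0.91,2.66,0.38,3.57,-3.57,2.39
PTP1B,ursolic-acid,-23.95,-6.06,0.21,6.27,6.06,-0.21,3.14,0.32,2.93,-2.93,1.36
DPP4,rutin,-49.36,-5.64,-1.66,3.98,5.64,1.66,1.99,0.5,3.65,-3.65,1.31
DPP4,Q37DG,-58.23,-5.68,-1.55,4.13,5.68,1.55,2.07,0.48,3.62,-3.62,3.16
DPP4,Q7G,-39.95,-5.84,-1.49,4.35,5.84,1.49,2.18,0.46,3.67,-3.67,3.09
DPP4,piperitol,-20.07,-6.28,0.38,6.66,6.28,-0.38,3.33,0.3,2.95,-2.95,1.31
DPP4,diosmetin,-23.11,-5.51,-0.06,5.45,5.51,0.06,2.73,0.37,2.79,-2.79,1.42
DPP4,sitagliptin,-24.10,-6.33,-0.63,5.70,6.33,0.63,2.85,2.85,0.35,-3.48,2.12
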