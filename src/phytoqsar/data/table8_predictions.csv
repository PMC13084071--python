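model,compound,descriptor_1,value_1,descriptor_2,value_2,descriptor_3,value_3,descriptor_4,value_4,descriptor_5,value_5,descriptor_6,value_6,descriptor_7,value_7,descriptor_8,value_8,pic50_pred,ic50_molar,mw,ic50_ug_ml
PTP1B,Diosmetin,R_TpiPCTPC,7.249,nRing,3,ATSC4m,24.31,GATS3p,1.084,fragC,114.06,MATS7e,-0.043,MAXDP,5.124,AATS3e,8.299,4.955,1.11E-05,300.26,3.33
PTP1B,Q37DG,R_TpiPCTPC,3.939,nRing,5,ATSC4m,-120.67,GATS3p,1.021,fragC,412.17,MATS7e,0.014,MAXDP,6.737,AATS3e,8.565,6.213,6.12E-07,626.50,0.38
PTP1B,Q7G,R_TpiPCTPC,4.419,nRing,4,ATSC4m,-135.32,GATS3p,1.071,fragC,240.12,MATS7e,0.086,MAXDP,5.654,AATS3e,8.513,5.531,2.95E-06,464.40,1.37
PTP1B,Rutin,R_TpiPCTPC,3.673,nRing,5,ATSC4m,-137.09,GATS3p,1.055,fragC,403.16,MATS7e,0.028,MAXDP,6.570,AATS3e,8.544,5.273,5.33E-06,610.50,3.26
PTP1B,Cadinene,R_TpiPCTPC,1.994,nRing,2,ATSC4m,-390.42,GATS3p,1.254,fragC,46.00,MATS7e,-0.364,MAXDP,0.500,AATS3e,7.141,5.978,1.05E-06,204.35,0.21
PTP1B,Piperitol,R_TpiPCTPC,3.251,nRing,5,ATSC4m,-495.29,GATS3p,1.212,fragC,250.06,MATS7e,-0.104,MAXDP,3.820,AATS3e,7.818,5.146,7.14E-06,356.40,2.55
DPP4,Diosmetin,SIC0,0.292,GATS7m,0.970,SpMax1_Bhv,3.913,JGT,0.538,apol,40.97,SpMin2_Bhv,1.891,ATSC6p,2.007,AATSC8p,-0.046,5.398,4.00E-06,300.26,1.20
DPP4,Q37DG,SIC0,0.249,GATS7m,0.855,SpMax1_Bhv,3.984,JGT,0.556,apol,81.16,SpMin2_Bhv,1.899,ATSC6p,3.257,AATSC8p,-0.003,8.081,8.30E-09,626.50,0.01
DPP4,Q7G,SIC0,0.268,GATS7m,0.824,SpMax1_Bhv,3.935,JGT,0.561,apol,60.59,SpMin2_Bhv,1.911,ATSC6p,1.380,AATSC8p,-0.002,6.449,3.56E-07,464.40,0.17
DPP4,Rutin,SIC0,0.248,GATS7m,0.888,SpMax1_Bhv,3.896,JGT,0.565,apol,80.36,SpMin2_Bhv,1.909,ATSC6p,0.918,AATSC8p,-0.021,7.046,9.00E-08,610.50,0.05
DPP4,Cadinene,SIC0,0.182,GATS7m,1.253,SpMax1_Bhv,3.867,JGT,0.492,apol,42.40,SpMin2_Bhv,1.745,ATSC6p,-0.405,AATSC8p,0.109,8.540,2.88E-09,204.35,0.00
DPP4,Piperitol,SIC0,0.259,GATS7m,1.088,SpMax1_Bhv,3.899,JGT,0.407,apol,53.35,SpMin2_Bhv,1.928,ATSC6p,-2.051,AATSC8p,-0.048,4.828,1.48E-05,356.40,5.29
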