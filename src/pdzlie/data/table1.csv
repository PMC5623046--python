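complex_id,reference_group,in_fit,exp_ddg,exp_is_lower_bound,pb,vdw,sa,restraint,printed_comp_ddg,printed_uncertainty,printed_correction
Sdc1,sdc1,False,0.00,False,0.00,0.00,0.00,0.00,0.00,0.1,0.00
Sdc1.A0F,sdc1,True,0.43,False,0.19,-4.21,-47.95,0.00,0.16,0.1,0.00
Sdc1.E4K,sdc1,True,0.81,False,2.62,-0.17,-12.94,0.28,0.98,0.2,0.00
Sdc1.E4L,sdc1,True,0.56,False,1.95,-1.30,-8.08,0.00,0.49,0.2,0.00
"Sdc1.E3D,Y1T",sdc1,True,0.87,False,1.67,2.08,12.05,0.00,0.41,0.1,0.00
"Sdc1.E3T,Y1K",sdc1,True,1.33,False,1.49,3.49,15.64,0.00,0.38,0.1,0.00
Sdc1.F2I,sdc1,True,0.80,False,0.38,-0.44,-42.27,0.00,0.26,0.1,0.00
Sdc1.A0mA,sdc1,True,0.04,False,2.06,2.46,-13.51,0.00,0.62,0.1,0.00
Sdc3,sdc1,True,0.13,False,0.38,1.38,-23.06,0.00,0.21,0.1,0.00
Consensus,sdc1,True,0.84,False,2.72,3.35,67.97,0.00,0.48,0.1,0.00
YAAEKYWA,sdc1,True,0.72,False,2.10,4.73,64.29,0.00,0.36,0.1,0.00
YAAKAFRF,sdc1,True,1.17,False,4.70,5.02,53.73,0.29,1.35,0.1,0.00
YAAYRYRA,sdc1,True,1.32,True,4.07,1.66,-18.18,0.14,1.26,0.1,0.00
YAARKFAK,sdc1,True,1.32,True,3.81,7.13,5.44,0.23,1.30,0.1,0.00
YAAKRTYV,sdc1,True,1.32,True,3.72,8.01,49.20,0.25,1.14,0.1,0.00
YAAGRKHF,sdc1,True,1.32,True,3.49,2.11,14.15,0.66,1.52,0.2,0.00
YAALIHKF,sdc1,True,1.32,True,2.70,1.16,-2.87,0.27,0.98,0.1,0.00
YAAQKHFH,sdc1,True,1.32,True,2.59,-1.74,-34.81,0.17,0.92,0.2,0.00
QM:CADM1,sdc1,True,0.87,False,5.74,4.77,24.95,0.00,1.43,0.2,0.00
L911M:Sdc1,sdc1,True,0.15,False,0.62,-1.03,-45.29,0.00,0.32,0.2,0.00
K912E:Sdc1,sdc1,True,0.97,False,2.27,-0.99,-8.66,0.00,0.58,0.2,0.00
"L911M,K912E:Sdc1",sdc1,True,1.21,False,1.71,-1.52,-35.42,0.00,0.54,0.1,0.00
L915F:Sdc1,sdc1,True,0.65,False,0.04,-0.98,-13.78,0.00,0.05,0.2,0.00
L920V:Sdc1,sdc1,True,0.31,False,-1.10,0.17,-48.56,0.01,-0.07,0.2,0.00
"L915F,L920V:Sdc1",sdc1,True,1.32,False,-0.24,1.03,-27.04,0.12,0.19,0.2,0.00
QM:Sdc1,sdc1,True,0.89,False,-0.02,-0.83,-71.82,0.00,0.27,0.1,0.00
QM:Sdc1.A0F,sdc1,True,0.22,False,0.26,1.50,-26.96,0.00,0.20,0.2,0.00
QM:Casp,caspr4,False,-0.23,False,3.35,1.86,10.98,0.00,-0.23,0.1,-1.06
WT:Casp,caspr4,True,-0.21,False,2.04,2.77,32.77,0.26,-0.37,0.1,-1.06
WT:Caspr.F0A,caspr4,True,0.52,False,2.90,3.61,77.81,0.00,-0.57,0.1,-1.06
L911M:Casp,caspr4,True,-0.39,False,2.81,3.49,24.68,0.39,0.00,0.1,-1.06
K912E:Casp,caspr4,True,0.46,False,2.70,-0.44,-50.13,0.28,0.09,0.1,-1.06
"L911M,K912E:Casp",caspr4,True,0.04,False,3.41,2.57,22.74,0.24,-0.01,0.1,-1.06
L915F:Casp,caspr4,True,0.48,False,2.33,0.78,-2.68,0.00,-0.45,0.1,-1.06
L920V:Casp,caspr4,True,-0.54,False,2.29,-0.28,4.82,0.00,-0.51,0.1,-1.06
"L915F,L920V:Casp",caspr4,True,0.62,False,2.49,-0.07,-17.92,0.00,-0.37,0.1,-1.06
QM:Caspr.F0A,caspr4,True,1.09,False,4.59,3.78,95.58,0.00,-0.22,0.1,-1.06
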