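complex_id,reference_group,in_fit,exp_ddg,exp_is_lower_bound,pb,vdw,sa,restraint,printed_comp_ddg,printed_uncertainty,printed_correction
Sdc1.A0M,sdc1,False,1.56,False,-0.51,-3.27,-36.08,0.00,-0.05,,0.00
Sdc1.A0V,sdc1,False,1.90,False,1.30,-2.40,-81.36,0.20,0.80,,0.00
Sdc2,sdc1,False,1.67,False,2.10,4.32,61.59,0.00,0.37,,0.00
Sdc4,sdc1,False,1.59,False,1.69,4.46,59.45,0.23,0.50,,0.00
QM:Neur,sdc1,False,0.32,False,0.70,3.98,12.96,0.00,0.20,,0.00
"L911M,K912E:Neur",sdc1,False,1.25,False,0.40,1.36,-39.92,0.00,0.29,,0.00
"L915F,L920V:Neur",sdc1,False,1.08,False,0.25,2.90,-11.94,0.00,0.17,,0.00
Sdc1.A0Q,sdc1,False,,False,1.06,-2.72,7.76,0.00,0.18,,0.00
Sdc1.F2C,sdc1,False,,False,1.15,0.81,-33.84,0.00,0.44,,0.00
Sdc1.F2M,sdc1,False,,False,0.06,0.87,5.57,0.00,0.01,,0.00
Sdc1.F2T,sdc1,False,,False,-0.05,-0.13,-45.20,0.00,0.17,,0.00
Sdc1.F2V,sdc1,False,,False,-0.46,-1.09,-48.83,0.00,0.06,,0.00
Sdc1.F2Y,sdc1,False,,False,-0.57,-1.63,-33.98,0.00,-0.04,,0.00
Casp.F0mA,caspr4,False,,False,4.55,2.25,8.80,0.00,0.09,,-1.06
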