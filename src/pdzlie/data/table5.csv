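peptide_id,folded_pct_run1,folded_pct_run2,printed_ddg_i,printed_uncertainty,ns_per_run
Sdc1,5.8,3.8,0.0,0.2,200
A0F,3.4,0.3,0.9,0.8,100
A0N,3.6,0.6,0.7,0.7,100
A0M,4.0,0.8,0.6,0.6,100
E4K,5.0,3.2,0.1,0.3,100
F2I,1.1,1.1,0.9,0.1,100
"E3D,T1T",4.6,0.6,0.6,0.7,100
Sdc2,2.0,0.8,0.8,0.4,100
Sdc3,0.7,0.6,1.2,0.1,100
Caspr4,2.6,8.6,0.0,0.5,200
Caspr4-F0A,5.7,1.6,0.3,0.5,200
YAAEKYWA,8.4,0.1,1.0,1.6,200
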