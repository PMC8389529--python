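id,dg_b,dg_v,dg_standard,dg_standard_err,rank_comp,dg_exp,dg_exp_err,rank_exp
G2,-7.7,0.0,-7.7,0.1,6,-7.66,0.05,5
G3,-9.6,-0.1,-9.7,0.1,3,-6.45,0.06,6
G6,-9.3,0.4,-8.9,0.1,5,-8.34,0.05,3
G7,-10.8,0.3,-10.6,0.1,2,-10.0,0.1,2
G8,-12.9,0.4,-12.5,0.1,1,-13.50,0.04,1
G10,-9.4,0.2,-9.1,0.1,4,-8.22,0.07,4
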