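id,dg_b,dg_v,dg_standard,dg_standard_err,rank_comp,dg_exp,dg_exp_err,rank_exp
1,-13.6,-0.2,-13.8,0.1,1,-13.3,,1
2,-7.1,-0.7,-7.8,0.3,7,-11.4,,3
3,-10.4,-0.5,-10.9,0.0,3,-10.5,,6
4,-10.1,-0.1,-10.2,0.2,4,-12.6,,2
5,-11.5,-0.2,-11.7,0.1,2,-10.9,,4
6,-7.6,-0.3,-8.0,0.1,6,-9.7,,7
7,-4.2,-0.4,-4.6,0.8,8,-8.5,,8
8,-9.9,-0.3,-10.2,0.9,5,-10.6,,5
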