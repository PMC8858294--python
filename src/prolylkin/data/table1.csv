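variant,kd_if_uM,dh_if_kcal_mol,kd_fkbp_uM,dh_fkbp_kcal_mol,activity_wt_per_uM_s,kd_dif_uM,dh_dif_kcal_mol,activity_dif_per_uM_s
psWT,0.22,-15.4,3.5,-6.4,4.9,15.6,-12,2.2
R2A,,,,,5.1,,,1.3
Y3A,0.72,-13.1,17.3,-11.3,3.9,51.5,-9.3,2.5
W4A,0.75,-15.6,8.4,-6.6,2.0,30.8,-6.6,1.1
W4E,0.86,-15.2,13.9,-5.1,4.4,19.6,-3.8,0.9
W4K,0.21,-15.5,3.2,-3.1,2.2,12.6,-4.4,3.5
M8A,0.24,-18.5,6.0,-9.3,7.7,19.4,-10,3.1
F13A,0.38,-17.6,6.4,-6.4,3.1,22.7,-15,0.4
F13E,1.15,-20.8,10.4,-5.0,7.0,36.1,-13,0.1
F13K,0.11,-18.1,5.2,-5.2,3.4,20.0,-10,2.3
G14M,0.10,-16.6,2.2,-8.2,,8.3,-11,
A15L,0.16,-14.3,4.1,-6.5,,14.8,-10,
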