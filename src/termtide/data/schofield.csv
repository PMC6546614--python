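sex,age_min,age_max,slope_mj_per_kg,intercept_mj
male,3,10,0.095,2.110
male,10,18,0.074,2.754
female,3,10,0.085,2.033
female,10,18,0.056,2.898
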