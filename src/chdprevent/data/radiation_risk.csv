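sex,cancer,risk_per_100k,anchor_age
male,lung,6.528,45
male,leukemia,1.01,45
female,lung,15.04,55
female,breast,3.88,55
female,leukemia,0.72,55
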