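sex,age_lo,age_hi,prevalence
male,45,54,0.99
male,55,64,0.99
male,65,75,0.99
female,55,64,0.45
female,65,75,0.55
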