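sex,age_lo,age_hi,frs_cat,probability
male,45,54,0-5,0.28
male,45,54,5-10,0.38
male,45,54,10-15,0.16
male,45,54,15-20,0.09
male,45,54,>20,0.09
male,55,64,0-5,0.12
male,55,64,5-10,0.32
male,55,64,10-15,0.22
male,55,64,15-20,0.16
male,55,64,>20,0.18
male,65,75,0-5,0.05
male,65,75,5-10,0.24
male,65,75,10-15,0.22
male,65,75,15-20,0.19
male,65,75,>20,0.3
female,55,64,0-5,0.72
female,55,64,5-10,0.245
female,55,64,10-15,0.025
female,55,64,15-20,0.007
female,55,64,>20,0.003
female,65,75,0-5,0.56
female,65,75,5-10,0.35
female,65,75,10-15,0.065
female,65,75,15-20,0.018
female,65,75,>20,0.007
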