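sex,age_lo,age_hi,cac_cat,probability
male,45,54,0,0.62
male,45,54,1-100,0.25
male,45,54,101-400,0.09
male,45,54,401-1000,0.03
male,45,54,>1000,0.01
male,55,64,0,0.42
male,55,64,1-100,0.3
male,55,64,101-400,0.17
male,55,64,401-1000,0.075
male,55,64,>1000,0.035
male,65,75,0,0.26
male,65,75,1-100,0.3
male,65,75,101-400,0.24
male,65,75,401-1000,0.13
male,65,75,>1000,0.07
female,55,64,0,0.68
female,55,64,1-100,0.21
female,55,64,101-400,0.08
female,55,64,401-1000,0.022
female,55,64,>1000,0.008
female,65,75,0,0.49
female,65,75,1-100,0.28
female,65,75,101-400,0.15
female,65,75,401-1000,0.057
female,65,75,>1000,0.023
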