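sex,age_lo,age_hi,statin_rate,aspirin_rate
male,35,44,0.048,0.161
male,45,54,0.114,0.288
male,55,64,0.301,0.441
male,65,74,0.377,0.537
male,75,105,0.303,0.551
female,35,44,0.03,0.111
female,45,54,0.072,0.226
female,55,64,0.186,0.379
female,65,74,0.329,0.475
female,75,105,0.299,0.508
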