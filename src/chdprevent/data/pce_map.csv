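sex,frs,pce
male,0.0,0.0
male,0.05,0.034
male,0.075,0.051
male,0.1,0.068
male,0.15,0.102
male,0.2,0.136
male,0.3,0.204
male,0.35,0.238
female,0.0,0.0
female,0.05,0.05
female,0.075,0.075
female,0.1,0.1
female,0.15,0.15
female,0.2,0.2
female,0.3,0.3
female,0.35,0.35
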