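sex,frs_cat,median,lower95,upper95
male,0-5,0.9,0.5,2.0
male,5-10,1.1,0.5,2.0
male,10-15,1.7,1.0,3.4
male,15-20,2.0,1.0,4.0
male,>20,2.5,1.2,4.6
female,0-5,1.9,0.6,4.6
female,5-10,1.9,0.6,4.2
female,10-15,2.5,1.5,4.8
female,15-20,3.1,1.8,5.6
female,>20,3.8,1.7,7.6
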