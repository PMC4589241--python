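sex,frs_cat,mean,sd
male,0-5,112,30.0
male,5-10,116,30.0
male,10-15,120,30.0
male,15-20,124,30.0
male,>20,128,30.0
female,0-5,124,32.0
female,5-10,130,32.0
female,10-15,136,32.0
female,15-20,141,32.0
female,>20,146,32.0
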