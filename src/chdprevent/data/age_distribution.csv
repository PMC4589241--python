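sex,age,weight
male,45,1.0
male,46,0.985
male,47,0.97
male,48,0.955
male,49,0.94
male,50,0.925
male,51,0.91
male,52,0.895
male,53,0.88
male,54,0.865
male,55,0.85
male,56,0.835
male,57,0.82
male,58,0.805
male,59,0.79
male,60,0.775
male,61,0.76
male,62,0.745
male,63,0.73
male,64,0.715
male,65,0.7
male,66,0.685
male,67,0.67
male,68,0.655
male,69,0.64
male,70,0.625
male,71,0.61
male,72,0.595
male,73,0.58
male,74,0.565
male,75,0.55
female,55,1.0
female,56,0.9825
female,57,0.965
female,58,0.9475
female,59,0.93
female,60,0.9125
female,61,0.895
female,62,0.8775
female,63,0.86
female,64,0.8425
female,65,0.825
female,66,0.8075
female,67,0.79
female,68,0.7725
female,69,0.755
female,70,0.7375
female,71,0.72
female,72,0.7025
female,73,0.685
female,74,0.6675
female,75,0.65
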