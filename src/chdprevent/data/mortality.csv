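sex,age,annual_prob
male,45,0.003
male,46,0.003215
male,47,0.003446
male,48,0.003693
male,49,0.003958
male,50,0.004242
male,51,0.004547
male,52,0.004873
male,53,0.005223
male,54,0.005597
male,55,0.005999
male,56,0.00643
male,57,0.006891
male,58,0.007385
male,59,0.007915
male,60,0.008483
male,61,0.009092
male,62,0.009745
male,63,0.010444
male,64,0.011193
male,65,0.011996
male,66,0.012857
male,67,0.01378
male,68,0.014769
male,69,0.015829
male,70,0.016964
male,71,0.018182
male,72,0.019486
male,73,0.020885
male,74,0.022383
male,75,0.023989
male,76,0.025711
male,77,0.027556
male,78,0.029533
male,79,0.031652
male,80,0.033924
male,81,0.036358
male,82,0.038967
male,83,0.041763
male,84,0.04476
male,85,0.047972
male,86,0.051414
male,87,0.055103
male,88,0.059058
male,89,0.063295
male,90,0.067837
male,91,0.072705
male,92,0.077922
male,93,0.083514
male,94,0.089507
male,95,0.095929
male,96,0.102813
male,97,0.110191
male,98,0.118098
male,99,0.126572
male,100,0.135655
male,101,0.145389
male,102,0.155822
male,103,0.167003
male,104,0.178987
male,105,0.191831
female,55,0.0033
female,56,0.003592
female,57,0.00391
female,58,0.004256
female,59,0.004633
female,60,0.005043
female,61,0.005489
female,62,0.005975
female,63,0.006503
female,64,0.007079
female,65,0.007705
female,66,0.008387
female,67,0.00913
female,68,0.009938
female,69,0.010817
female,70,0.011774
female,71,0.012816
female,72,0.013951
female,73,0.015185
female,74,0.016529
female,75,0.017992
female,76,0.019584
female,77,0.021317
female,78,0.023204
female,79,0.025257
female,80,0.027493
female,81,0.029926
female,82,0.032574
female,83,0.035457
female,84,0.038595
female,85,0.042011
female,86,0.045729
female,87,0.049775
female,88,0.054181
female,89,0.058976
female,90,0.064195
female,91,0.069876
female,92,0.07606
female,93,0.082791
female,94,0.090118
female,95,0.098094
female,96,0.106775
female,97,0.116224
female,98,0.12651
female,99,0.137706
female,100,0.149893
female,101,0.163159
female,102,0.177598
female,103,0.193315
female,104,0.210424
female,105,0.229046
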