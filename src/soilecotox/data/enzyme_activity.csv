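dose,time,variable,value
0.000,30,dehydrogenases,5.310
0.000,60,dehydrogenases,9.151
0.000,90,dehydrogenases,7.255
0.075,30,dehydrogenases,5.412
0.075,60,dehydrogenases,9.529
0.075,90,dehydrogenases,6.645
2.250,30,dehydrogenases,5.386
2.250,60,dehydrogenases,9.676
2.250,90,dehydrogenases,6.621
11.25,30,dehydrogenases,5.211
11.25,60,dehydrogenases,9.525
11.25,90,dehydrogenases,6.489
22.50,30,dehydrogenases,5.087
22.50,60,dehydrogenases,8.808
22.50,90,dehydrogenases,6.309
0.000,30,catalase,0.360
0.000,60,catalase,0.346
0.000,90,catalase,0.334
0.075,30,catalase,0.335
0.075,60,catalase,0.331
0.075,90,catalase,0.331
2.250,30,catalase,0.329
2.250,60,catalase,0.302
2.250,90,catalase,0.321
11.25,30,catalase,0.299
11.25,60,catalase,0.290
11.25,90,catalase,0.272
22.50,30,catalase,0.275
22.50,60,catalase,0.272
22.50,90,catalase,0.262
0.000,30,urease,0.175
0.000,60,urease,0.165
0.000,90,urease,0.136
0.075,30,urease,0.164
0.075,60,urease,0.165
0.075,90,urease,0.132
2.250,30,urease,0.148
2.250,60,urease,0.134
2.250,90,urease,0.129
11.25,30,urease,0.137
11.25,60,urease,0.130
11.25,90,urease,0.109
22.50,30,urease,0.131
22.50,60,urease,0.110
22.50,90,urease,0.092
0.000,30,acid_phosphatase,0.910
0.000,60,acid_phosphatase,0.878
0.000,90,acid_phosphatase,0.863
0.075,30,acid_phosphatase,0.902
0.075,60,acid_phosphatase,0.837
0.075,90,acid_phosphatase,0.828
2.250,30,acid_phosphatase,0.869
2.250,60,acid_phosphatase,0.790
2.250,90,acid_phosphatase,0.774
11.25,30,acid_phosphatase,0.760
11.25,60,acid_phosphatase,0.740
11.25,90,acid_phosphatase,0.716
22.50,30,acid_phosphatase,0.705
22.50,60,acid_phosphatase,0.694
22.50,90,acid_phosphatase,0.686
0.000,30,alkaline_phosphatase,1.276
0.000,60,alkaline_phosphatase,2.259
0.000,90,alkaline_phosphatase,0.470
0.075,30,alkaline_phosphatase,1.091
0.075,60,alkaline_phosphatase,2.282
0.075,90,alkaline_phosphatase,0.496
2.250,30,alkaline_phosphatase,1.064
2.250,60,alkaline_phosphatase,2.229
2.250,90,alkaline_phosphatase,0.490
11.25,30,alkaline_phosphatase,1.055
11.25,60,alkaline_phosphatase,2.130
11.25,90,alkaline_phosphatase,0.431
22.50,30,alkaline_phosphatase,1.043
22.50,60,alkaline_phosphatase,2.090
22.50,90,alkaline_phosphatase,0.406
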