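dose,time,variable,value
0.000,30,organotrophic_bacteria,10.186
0.000,60,organotrophic_bacteria,10.474
0.000,90,organotrophic_bacteria,10.459
0.075,30,organotrophic_bacteria,10.294
0.075,60,organotrophic_bacteria,10.420
0.075,90,organotrophic_bacteria,10.425
2.250,30,organotrophic_bacteria,10.315
2.250,60,organotrophic_bacteria,10.311
2.250,90,organotrophic_bacteria,10.428
11.25,30,organotrophic_bacteria,10.384
11.25,60,organotrophic_bacteria,10.270
11.25,90,organotrophic_bacteria,10.395
22.50,30,organotrophic_bacteria,10.406
22.50,60,organotrophic_bacteria,10.192
22.50,90,organotrophic_bacteria,10.282
0.000,30,actinomycetes,9.938
0.000,60,actinomycetes,10.288
0.000,90,actinomycetes,10.293
0.075,30,actinomycetes,10.153
0.075,60,actinomycetes,10.199
0.075,90,actinomycetes,10.232
2.250,30,actinomycetes,10.087
2.250,60,actinomycetes,10.190
2.250,90,actinomycetes,10.217
11.25,30,actinomycetes,9.992
11.25,60,actinomycetes,10.168
11.25,90,actinomycetes,10.206
22.50,30,actinomycetes,9.941
22.50,60,actinomycetes,10.137
22.50,90,actinomycetes,10.175
0.000,30,fungi,7.153
0.000,60,fungi,7.348
0.000,90,fungi,7.440
0.075,30,fungi,7.112
0.075,60,fungi,7.26
0.075,90,fungi,7.285
2.250,30,fungi,6.878
2.250,60,fungi,7.128
2.250,90,fungi,7.203
11.25,30,fungi,6.894
11.25,60,fungi,7.073
11.25,90,fungi,7.112
22.50,30,fungi,6.858
22.50,60,fungi,6.951
22.50,90,fungi,7.014
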