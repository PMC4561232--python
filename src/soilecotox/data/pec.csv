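dose,time,value
0.075,30,0.0049
0.075,60,0.0038
0.075,90,0.0029
2.250,30,0.1465
2.250,60,0.1146
2.250,90,0.0896
11.25,30,0.7330
11.25,60,0.5731
11.25,90,0.4481
22.50,30,1.4660
22.50,60,1.1462
22.50,90,0.8961
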