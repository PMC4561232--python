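dose,variable,value
0.075,dehydrogenases,-0.467
2.250,dehydrogenases,-0.467
11.25,dehydrogenases,-0.508
22.50,dehydrogenases,-0.551
0.075,catalase,-0.818
2.250,catalase,-0.866
11.25,catalase,-0.624
22.50,catalase,-0.449
0.075,urease,-0.491
2.250,urease,-0.468
11.25,urease,-0.225
22.50,urease,-0.062
0.075,acid_phosphatase,-0.786
2.250,acid_phosphatase,-0.647
11.25,acid_phosphatase,-0.536
22.50,acid_phosphatase,-0.485
0.075,alkaline_phosphatase,0.235
2.250,alkaline_phosphatase,0.243
11.25,alkaline_phosphatase,0.330
22.50,alkaline_phosphatase,0.374
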