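dose,time,variable,value
0.075,30,dehydrogenases,0.949
0.075,60,dehydrogenases,0.925
0.075,90,dehydrogenases,0.817
2.250,30,dehydrogenases,0.884
2.250,60,dehydrogenases,0.898
2.250,90,dehydrogenases,0.828
11.25,30,dehydrogenases,0.931
11.25,60,dehydrogenases,0.920
11.25,90,dehydrogenases,0.793
22.50,30,dehydrogenases,0.878
22.50,60,dehydrogenases,0.918
22.50,90,dehydrogenases,0.743
0.075,30,catalase,0.863
0.075,60,catalase,0.870
0.075,90,catalase,0.878
2.250,30,catalase,0.832
2.250,60,catalase,0.610
2.250,90,catalase,0.917
11.25,30,catalase,0.667
11.25,60,catalase,0.682
11.25,90,catalase,0.626
22.50,30,catalase,0.529
22.50,60,catalase,0.573
22.50,90,catalase,0.568
0.075,30,urease,0.877
0.075,60,urease,0.908
0.075,90,urease,0.803
2.250,30,urease,0.690
2.250,60,urease,0.635
2.250,90,urease,0.895
11.25,30,urease,0.573
11.25,60,urease,0.567
11.25,90,urease,0.603
22.50,30,urease,0.501
22.50,60,urease,0.337
22.50,90,urease,0.366
0.075,30,acid_phosphatase,0.913
0.075,60,acid_phosphatase,0.893
0.075,90,acid_phosphatase,0.901
2.250,30,acid_phosphatase,0.893
2.250,60,acid_phosphatase,0.802
2.250,90,acid_phosphatase,0.799
11.25,30,acid_phosphatase,0.675
11.25,60,acid_phosphatase,0.690
11.25,90,acid_phosphatase,0.663
22.50,30,acid_phosphatase,0.552
22.50,60,acid_phosphatase,0.584
22.50,90,acid_phosphatase,0.592
0.075,30,alkaline_phosphatase,0.711
0.075,60,alkaline_phosphatase,0.964
0.075,90,alkaline_phosphatase,0.905
2.250,30,alkaline_phosphatase,0.667
2.250,60,alkaline_phosphatase,0.968
2.250,90,alkaline_phosphatase,0.922
11.25,30,alkaline_phosphatase,0.654
11.25,60,alkaline_phosphatase,0.886
11.25,90,alkaline_phosphatase,0.836
22.50,30,alkaline_phosphatase,0.633
22.50,60,alkaline_phosphatase,0.851
22.50,90,alkaline_phosphatase,0.727
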