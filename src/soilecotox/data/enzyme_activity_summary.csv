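variable,time,statistic,value,significant
dehydrogenases,30,mean,5.281,
dehydrogenases,60,mean,9.338,
dehydrogenases,90,mean,6.664,
catalase,30,mean,0.320,
catalase,60,mean,0.308,
catalase,90,mean,0.304,
urease,30,mean,0.151,
urease,60,mean,0.141,
urease,90,mean,0.119,
acid_phosphatase,30,mean,0.829,
acid_phosphatase,60,mean,0.788,
acid_phosphatase,90,mean,0.773,
alkaline_phosphatase,30,mean,1.106,
alkaline_phosphatase,60,mean,2.198,
alkaline_phosphatase,90,mean,0.458,
dehydrogenases,30,r,-0.945,1
dehydrogenases,60,r,-0.652,0
dehydrogenases,90,r,-0.727,0
catalase,30,r,-0.946,1
catalase,60,r,-0.884,1
catalase,90,r,-0.952,1
urease,30,r,-0.860,0
urease,60,r,-0.892,1
urease,90,r,-0.993,1
acid_phosphatase,30,r,-0.978,1
acid_phosphatase,60,r,-0.925,1
acid_phosphatase,90,r,-0.908,1
alkaline_phosphatase,30,r,-0.555,0
alkaline_phosphatase,60,r,-0.961,1
alkaline_phosphatase,90,r,-0.942,1
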