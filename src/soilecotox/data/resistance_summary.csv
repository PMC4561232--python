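variable,time,statistic,value,significant
dehydrogenases,30,mean,0.911,
dehydrogenases,60,mean,0.915,
dehydrogenases,90,mean,0.795,
catalase,30,mean,0.723,
catalase,60,mean,0.684,
catalase,90,mean,0.747,
urease,30,mean,0.660,
urease,60,mean,0.612,
urease,90,mean,0.667,
acid_phosphatase,30,mean,0.758,
acid_phosphatase,60,mean,0.742,
acid_phosphatase,90,mean,0.739,
alkaline_phosphatase,30,mean,0.666,
alkaline_phosphatase,60,mean,0.917,
alkaline_phosphatase,90,mean,0.847,
dehydrogenases,30,r,-0.519,0
dehydrogenases,60,r,0.210,0
dehydrogenases,90,r,-0.972,1
catalase,30,r,-0.997,1
catalase,60,r,-0.656,0
catalase,90,r,-0.933,1
urease,30,r,-0.933,1
urease,60,r,-0.918,1
urease,90,r,-0.969,1
acid_phosphatase,30,r,-0.986,1
acid_phosphatase,60,r,-0.975,1
acid_phosphatase,90,r,-0.951,1
alkaline_phosphatase,30,r,-0.874,0
alkaline_phosphatase,60,r,-0.972,1
alkaline_phosphatase,90,r,-0.984,1
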