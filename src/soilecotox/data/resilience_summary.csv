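variable,statistic,value,significant
dehydrogenases,mean,-0.498,
catalase,mean,-0.689,
urease,mean,-0.312,
acid_phosphatase,mean,-0.614,
alkaline_phosphatase,mean,0.296,
dehydrogenases,r,-0.996,1
catalase,r,0.979,1
urease,r,0.991,1
acid_phosphatase,r,0.902,0
alkaline_phosphatase,r,0.982,1
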