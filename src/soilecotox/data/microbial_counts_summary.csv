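variable,time,statistic,value,significant
organotrophic_bacteria,30,mean,10.320,
organotrophic_bacteria,60,mean,10.340,
organotrophic_bacteria,90,mean,10.400,
actinomycetes,30,mean,10.020,
actinomycetes,60,mean,10.200,
actinomycetes,90,mean,10.230,
fungi,30,mean,7.000,
fungi,60,mean,7.170,
fungi,90,mean,7.220,
organotrophic_bacteria,30,r,0.813,0
organotrophic_bacteria,60,r,-0.891,1
organotrophic_bacteria,90,r,-0.963,1
actinomycetes,30,r,-0.547,0
actinomycetes,60,r,-0.762,0
actinomycetes,90,r,-0.791,0
fungi,30,r,-0.709,0
fungi,60,r,-0.902,1
fungi,90,r,-0.876,1
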