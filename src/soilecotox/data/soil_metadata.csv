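parameter,value,unit
sand,69.41,% (2000-50 um)
silt,27.71,% (50-2 um)
clay,2.88,% (<2 um)
pH_KCl,7.00,-
hydrolytic_acidity,6.40,mmol(+) kg-1
total_exchangeable_bases,165.9,mmol(+) kg-1
organic_carbon,14.30,g kg-1
total_nitrogen,0.98,g kg-1
exchangeable_K,180.0,mg kg-1
exchangeable_Ca,2571.4,mg kg-1
exchangeable_Na,20.0,mg kg-1
exchangeable_Mg,59.5,mg kg-1
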