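study,year,ethnicity,source,n_case,n_control,case_GG,case_GA,case_AA,ctrl_GG,ctrl_GA,ctrl_AA
Bao 2011,2011,Asian,Hospital,160,320,64,71,25,141,151,28
Wang 2010,2010,Asian,Population,672,693,298,305,69,366,276,51
Pinto 2009,2009,Caucasian,Hospital,165,200,47,79,39,56,92,52
Liu 2009,2009,Asian,Hospital,168,194,75,78,15,92,86,16
Costa 2007,2007,Caucasian,Hospital,197,570,56,97,44,131,266,173
Vauleon 2007,2007,Caucasian,Population,209,214,44,102,63,31,120,63
Bhowmick 2004,2004,Caucasian,Hospital,42,76,15,16,11,12,37,27
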