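sample,total_phenols,tac,dpph_ic50,frap_ec50
n-Hexane,8,1.94,134.64,823.26
MeTHF,22.53,3.14,90.02,670.15
CPME,23.51,3.92,30.71,435.93
d-Limonene,22.35,2.05,101.45,580.62
p-Cymene,11.35,1.92,107.23,1045
Ethanol,21.54,0.34,197.56,807
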