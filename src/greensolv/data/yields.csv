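sample,extraction_yield
n-Hexane,50.84
MeTHF,54.91
CPME,58.82
d-Limonene,37.89
p-Cymene,24.64
Ethanol,27.29
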