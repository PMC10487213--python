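row,n-Hexane,MeTHF,CPME,d-Limonene,p-Cymene,Ethanol
SFA,14.57,15.71,12.59,15.66,18.10,16.20
MUFA,42.94,39.82,42.42,44.76,40.99,40.97
PUFA,44.32,42.56,43.58,39.52,39.59,43.57
PUFA/SFA,3.04,2.70,3.46,2.52,2.18,2.68
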