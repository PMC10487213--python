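component,n-Hexane,MeTHF,CPME,d-Limonene,p-Cymene,Ethanol
alpha-Tocopherol,1.56,1.61,62.7,1.75,0.83,1.35
gamma-Tocopherol,43.44,46.65,48.74,39.51,39.19,36.37
delta-Tocopherol,3.50,2.17,2.92,4.21,3.67,2.06
Total,48,50.6,52.3,44.8,43.7,39.8
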