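solute,n-Hexane,MeTHF,CPME,d-Limonene,p-Cymene,Ethanol
C16:0,1.77,0.57,0.87,0.73,1.26,2.94
C18:1,1.77,0.65,0.94,0.68,1.12,3.03
C18:2,1.95,0.75,1.17,0.82,1.23,2.98
gamma-Tocopherol,2.03,1.41,1.97,0.31,1.96,5.80
beta-Sitosterol,2.00,1.24,1.89,0.30,1.87,5.90
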