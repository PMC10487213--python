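solute,n-Hexane,MeTHF,CPME,d-Limonene,p-Cymene,Ethanol
C16:0,-1.27,0.0,0.0,-0.96,-1.03,-0.001
C18:1,-1.34,0.0,0.0,-0.98,-1.03,-0.05
C18:2,-1.31,0.0,0.0,-0.88,-0.9,0.0
gamma-Tocopherol,-0.2974,0.0,0.0,-0.1324,-0.2018,-0.8650
beta-Sitosterol,-0.8017,0.0,0.0,-0.6992,-0.7829,-0.5797
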