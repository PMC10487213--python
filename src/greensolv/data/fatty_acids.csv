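code,n-Hexane,MeTHF,CPME,d-Limonene,p-Cymene,Ethanol
C8:0,0.02,0.43,0.05,0.48,0.45,0.05
C14:0,0.01,0.05,0.08,0.54,0.11,0.01
C16:0,10.71,8.94,8.14,9.57,10.5,9.86
C16:1,0.05,0.32,0.31,0.33,0.33,0.06
C18:0,3.74,5.22,4.15,5.07,6.67,6.01
C18:1,42.77,39.27,42.08,44.35,40.46,40.79
C18:2,43.99,42.17,43.41,39.38,38.88,43.18
C18:3,0.33,0.39,0.17,0.14,0.71,0.39
C20:0,0.09,1.07,0.17,0.10,0.37,0.27
C20:1,0.12,0.23,0.03,0.08,0.20,0.12
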