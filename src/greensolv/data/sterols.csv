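component,n-Hexane,MeTHF,CPME,d-Limonene,p-Cymene,Ethanol
Cholesterol,1.13,1.47,0.46,4.83,5.15,6.64
Campesterol,99.22,123.20,164.53,101.00,86.93,66.79
Stigmasterol,33.39,25.89,16.64,29.61,38.11,37.92
beta-Sitosterol,373.63,437.80,555.93,400.78,364.19,387.96
D5-Avenasterol,40.21,37.37,39.48,41.89,44.03,35.22
D7-Avenasterol,6.13,13.90,8.87,11.83,4.01,5.64
Total,568,641,785,590,543,588
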