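name,delta_d,delta_p,delta_h,boiling_point,log_p,molecular_weight,viscosity,resource,cmr_class
n-Hexane,13.9,0.1,0.1,68.5,3.94,86.2,0.31,Petroleum,2
MeTHF,15,4.7,3.9,80,0.82,86.1,0.6,Cereal crop,
CPME,14.5,3.4,2.8,105.3,1.41,100.2,0.55,Chemical synthesis,
d-Limonene,13.9,1.8,2.1,175.4,4.45,136.2,0.923,Cereal crop,
p-Cymene,14.6,2.2,1.3,173.9,4.02,134.2,0.79,Wood,
Ethanol,14,9.1,15.2,72.6,-0.19,46.1,1.095,Cereal crop,
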