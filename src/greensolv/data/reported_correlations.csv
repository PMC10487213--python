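endpoint,driver,r_reported
tac,total_sterols,0.959
tac,total_tocopherols,0.841
tac,total_phenols,0.600
dpph_ic50,total_sterols,-0.913
dpph_ic50,total_tocopherols,0.700
dpph_ic50,total_phenols,-0.666
frap_ec50,total_sterols,-0.882
frap_ec50,total_phenols,-0.739
frap_ec50,total_tocopherols,-0.600
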