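# Dry air density [kg/m^3] vs temperature at 1 atm.
# Source: Perry's Chemical Engineers' Handbook.
T_K,value
243.15,1.455
273.15,1.293
293.15,1.205
313.15,1.127
373.15,0.946
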