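# Dry air specific heat capacity [J/(kg K)] vs temperature at 1 atm.
T_K,value
243.15,1006.0
273.15,1005.0
293.15,1005.0
313.15,1007.0
373.15,1012.0
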