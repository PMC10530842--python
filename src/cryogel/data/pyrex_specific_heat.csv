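# Pyrex glass specific heat capacity [J/(kg K)] vs temperature.
T_K,value
223.15,600.0
273.15,728.0
323.15,780.0
373.15,840.0
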