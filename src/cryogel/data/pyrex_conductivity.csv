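# Pyrex glass thermal conductivity [W/(m K)] vs temperature.
T_K,value
223.15,1.0
273.15,1.09
323.15,1.14
373.15,1.18
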