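# Pyrex (borosilicate) glass density [kg/m^3], constant.
T_K,value
293.15,2230.0
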