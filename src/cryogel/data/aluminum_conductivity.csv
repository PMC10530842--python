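# Aluminum thermal conductivity [W/(m K)], constant (4.007 W/(K cm) = 400.7 W/(m K)).
T_K,value
293.15,400.7
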