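# Latent heat of fusion of water [J/kg], constant.
T_K,value
273.15,334000.0
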