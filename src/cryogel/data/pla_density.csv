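# Polylactic acid (PLA) density [kg/m^3], constant.
T_K,value
293.15,1252.0
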