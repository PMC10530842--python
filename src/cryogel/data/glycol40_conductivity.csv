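# 40% w/w aqueous ethylene glycol thermal conductivity [W/(m K)] vs temperature.
# Sources: Bohne et al. (1984); Engineering ToolBox below -10 degC.
T_K,value
248.15,0.415
263.15,0.432
273.15,0.442
293.15,0.463
313.15,0.48
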