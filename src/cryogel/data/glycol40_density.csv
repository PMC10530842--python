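# 40% w/w aqueous ethylene glycol density [kg/m^3] vs temperature.
# Sources: Bohne et al. (1984); Engineering ToolBox below -10 degC.
T_K,value
248.15,1077.0
263.15,1071.0
273.15,1067.0
293.15,1057.0
313.15,1045.0
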