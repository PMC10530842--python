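# 40% w/w aqueous ethylene glycol specific heat [J/(kg K)] vs temperature.
# Source: Engineering ToolBox, ethylene glycol heat-transfer fluid tables.
T_K,value
248.15,3390.0
263.15,3450.0
273.15,3494.0
293.15,3570.0
313.15,3645.0
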