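# Ice specific heat capacity [J/(kg K)] vs temperature.
# Source: Engineering ToolBox, ice thermal properties.
T_K,value
173.15,1389.0
213.15,1666.0
233.15,1801.0
253.15,1943.0
268.15,2027.0
273.15,2050.0
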