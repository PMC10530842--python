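# Ice thermal conductivity [W/(m K)] vs temperature.
# Source: Engineering ToolBox, ice thermal properties.
T_K,value
173.15,3.48
213.15,2.76
233.15,2.45
253.15,2.25
268.15,2.23
273.15,2.22
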