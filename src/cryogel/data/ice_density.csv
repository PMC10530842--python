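# Ice density [kg/m^3] vs temperature.
# Source: Engineering ToolBox, ice thermal properties.
T_K,value
173.15,924.0
213.15,921.6
233.15,919.4
253.15,917.5
268.15,916.5
273.15,916.2
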