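# Liquid water density [kg/m^3] vs temperature.
# Source: Perry's Chemical Engineers' Handbook, 8th ed., Table 2-32 (rounded).
# Treated as constant below 0 degC (supercooled region).
T_K,value
273.15,999.8
283.15,999.7
293.15,998.2
313.15,992.2
333.15,983.2
353.15,971.8
363.15,965.3
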