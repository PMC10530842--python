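# Liquid water specific heat capacity [J/(kg K)] vs temperature.
# Source: Perry's Chemical Engineers' Handbook, 8th ed.
T_K,value
273.15,4217.0
283.15,4192.0
293.15,4184.0
313.15,4179.0
333.15,4185.0
353.15,4197.0
363.15,4205.0
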