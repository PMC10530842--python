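# Liquid water thermal conductivity [W/(m K)] vs temperature.
# Source: Perry's Chemical Engineers' Handbook, 8th ed.
T_K,value
273.15,0.561
283.15,0.58
293.15,0.598
313.15,0.631
333.15,0.654
353.15,0.67
363.15,0.675
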