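# Dry air thermal conductivity [W/(m K)] vs temperature.
# Source: Perry's Chemical Engineers' Handbook.
T_K,value
243.15,0.0216
273.15,0.0243
293.15,0.0257
313.15,0.0271
373.15,0.0314
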