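# PLA thermal conductivity [W/(m K)] vs temperature; constant below 48 degC.
# Source: literature data for amorphous PLA.
T_K,value
321.15,0.13
353.15,0.16
373.15,0.19
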