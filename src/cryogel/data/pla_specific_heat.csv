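# PLA specific heat capacity [J/(kg K)] vs temperature; constant below 55 degC.
# Source: literature data for amorphous PLA.
T_K,value
328.15,1590.0
353.15,1800.0
373.15,1955.0
423.15,2060.0
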