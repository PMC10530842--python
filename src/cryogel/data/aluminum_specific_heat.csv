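# Aluminum specific heat capacity [J/(kg K)] vs temperature.
# Source: McBride et al., NASA thermodynamic data (rounded).
T_K,value
223.15,861.0
273.15,893.0
323.15,918.0
373.15,938.0
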