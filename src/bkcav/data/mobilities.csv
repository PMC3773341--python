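ion,valence,limiting_equivalent_conductance
Na,1,50.1
K,1,73.5
Cl,-1,76.3
Gluconate,-1,24.3
Mg,2,53.1
Ca,2,59.5
HEPES,-1,22.1
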