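crop,storage_temp_C,target_ppf,structure_usd_per_m2,shelving_usd_per_m2,luminaires_usd_per_m2,chiller_usd_per_m2,total_capital_usd_per_m2,electricity_usd_per_m2_week,plants_per_m2_footprint
tomato,10,5,533.47,84.61,28.56,24.53,671.16,0.79,3307
watermelon,12,12,533.47,84.61,65.28,24.53,707.88,2.21,2116
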