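crop,scenario,storage,max_workers,min_workers,avg_workers,avg_workers_sd,peak_cost_usd_per_plant,peak_cost_sd,overall_cost_usd_per_plant,overall_cost_sd
tomato,1,yes,27,15,18,3.3,0.054,0.0014,0.049,0.0024
tomato,1,no,52,15,19,11,0.063,0.0016,0.05,0.0047
tomato,2,yes,23,13,19,2.9,0.051,0.0013,0.048,0.0023
tomato,2,no,46,13,20,11,0.06,0.0016,0.049,0.0041
tomato,3,yes,36,13,22,6.0,0.054,0.0014,0.047,0.0037
tomato,3,no,68,13,22,13,0.07,0.0018,0.048,0.006
watermelon,1,yes,62,30,39,11,0.11,0.0019,0.098,0.006
watermelon,1,no,99,30,40,26,0.13,0.0023,0.1,0.014
watermelon,2,yes,59,26,43,12,0.1,0.0017,0.097,0.0057
watermelon,2,no,85,26,44,23,0.12,0.0021,0.097,0.011
watermelon,3,yes,74,25,47,15,0.11,0.0019,0.094,0.0075
watermelon,3,no,124,25,48,26,0.157,0.0027,0.096,0.016
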