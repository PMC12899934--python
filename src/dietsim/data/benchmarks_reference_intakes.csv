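metric,reference_mean,iqr_low,iqr_high
energy_kcal,2100.0,1600,2500
protein_g,82.0,65,100
calcium_mg,950.0,650,1200
iron_mg,15.5,11,19
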