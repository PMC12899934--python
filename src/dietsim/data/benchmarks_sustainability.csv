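metric,comparison,reference,source
ghg_kgco2e,lt,5.0,EAT-Lancet 2019
water_l,lt,5000,Water footprint literature
iron_adequacy_pct,gt,90,DRI guidelines
calcium_adequacy_pct,gt,90,DRI guidelines
mediterranean_minus_western_ghg,lt,0,Literature consensus
diversity_score,range,8:15,FAO guidelines
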