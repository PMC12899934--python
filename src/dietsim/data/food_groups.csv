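group_name,energy_kcal_per_100g,protein_g_per_100g,iron_mg_per_100g,calcium_mg_per_100g,zinc_mg_per_100g,vitd_ug_per_100g,b12_ug_per_100g,ghg_kgco2e_per_kg,water_l_per_kg,price_usd_per_kg,energy_kcal_per_100g_sd,protein_g_per_100g_sd,iron_mg_per_100g_sd,calcium_mg_per_100g_sd,zinc_mg_per_100g_sd,vitd_ug_per_100g_sd,b12_ug_per_100g_sd,ghg_kgco2e_per_kg_sd,water_l_per_kg_sd,price_usd_per_kg_sd,n_foods
Animal,189.4,24.2,1.06,13.6,2.54,0.2543,0.3645,10.58,6678.0,11.5,68.8,5.6,0.89,3.4,1.27,0.1272,0.1822,9.22,4964.0,3.87,5
Dairy,275.0,10.5,0.54,204.8,1.3781,0.1896,0.3025,6.9,3293.0,6.14,285.9,9.5,0.76,291.0,0.6891,0.0948,0.1512,5.52,2280.0,5.62,5
Fruit,62.8,0.7,0.24,15.4,0.4183,0.3066,0.1365,0.92,633.0,3.46,16.8,0.3,0.13,14.4,0.2092,0.1533,0.0683,0.67,179.0,1.43,5
Grain,248.8,9.0,2.72,54.7,1.2928,0.0314,0.2687,2.07,2496.0,3.52,122.8,5.3,1.56,64.6,0.6464,0.0157,0.1343,0.69,1394.0,1.6,10
Legume,197.0,14.4,5.54,83.8,0.8013,0.315,0.1694,1.24,4460.0,4.08,140.3,12.4,5.68,108.7,0.4007,0.1575,0.0847,0.44,1427.0,0.82,5
Nuts,574.0,20.0,4.84,233.6,1.8036,0.199,0.2786,2.08,5371.0,17.1,59.8,4.2,1.84,235.5,0.9018,0.0995,0.1393,0.58,3488.0,6.84,5
Oil,701.4,0.4,0.3,6.6,1.7461,0.1734,0.4177,3.44,6348.0,8.6,310.6,0.9,0.28,9.0,0.873,0.0867,0.2089,1.61,4969.0,4.63,5
Vegetable,39.0,1.6,0.73,33.7,0.5045,0.0701,0.0648,1.03,276.0,2.78,24.1,0.8,0.73,26.6,0.2522,0.035,0.0324,0.65,74.0,0.96,10
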