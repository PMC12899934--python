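{
 "alpha0": 12.0,
 "mass_bounds_kg": [
  0.5,
  6.0
 ],
 "diversity": {
  "mean": 11.1,
  "sd": 2.0,
  "bounds": [
   4,
   20
  ]
 },
 "extension_densities_per_100g": {
  "groups": [
   "Animal",
   "Dairy",
   "Fruit",
   "Grain",
   "Legume",
   "Nuts",
   "Oil",
   "Vegetable"
  ],
  "zinc_mg": [
   2.54,
   1.3781,
   0.4183,
   1.2928,
   0.8013,
   1.8036,
   1.7461,
   0.5045
  ],
  "vitd_ug": [
   0.2543,
   0.1896,
   0.3066,
   0.0314,
   0.315,
   0.199,
   0.1734,
   0.0701
  ],
  "b12_ug": [
   0.3645,
   0.3025,
   0.1365,
   0.2687,
   0.1694,
   0.2786,
   0.4177,
   0.0648
  ]
 },
 "patterns": {
  "Mediterranean": {
   "base_shares": [
    0.071878,
    0.005132,
    0.476817,
    0.005132,
    0.051932,
    0.109511,
    0.048833,
    0.230765
   ],
   "concentration": 12.0,
   "mass_loc_kg": 1.9482,
   "mass_scale_kg": 0.4093,
   "age_mean": 42.5,
   "age_sd": 12.3,
   "bmi_mean": 24.8,
   "bmi_sd": 3.6,
   "female_fraction": 0.524,
   "income_mean": 3.2,
   "income_sd": 1.4,
   "tertiary_fraction": 0.453
  },
  "Western": {
   "base_shares": [
    0.080866,
    0.005163,
    0.6012649999999998,
    0.005163,
    0.066572,
    0.107483,
    0.053628,
    0.07986
   ],
   "concentration": 12.0,
   "mass_loc_kg": 1.9311,
   "mass_scale_kg": 0.5344,
   "age_mean": 38.7,
   "age_sd": 14.2,
   "bmi_mean": 27.3,
   "bmi_sd": 4.8,
   "female_fraction": 0.489,
   "income_mean": 2.8,
   "income_sd": 1.3,
   "tertiary_fraction": 0.327
  },
  "Plant-based": {
   "base_shares": [
    0.060917,
    0.019134,
    0.59222,
    0.065223,
    0.055538,
    0.097801,
    0.043151,
    0.066016
   ],
   "concentration": 12.0,
   "mass_loc_kg": 1.9695,
   "mass_scale_kg": 0.4181,
   "age_mean": 45.8,
   "age_sd": 11.6,
   "bmi_mean": 23.1,
   "bmi_sd": 3.2,
   "female_fraction": 0.562,
   "income_mean": 3.5,
   "income_sd": 1.3,
   "tertiary_fraction": 0.584
  },
  "Mixed": {
   "base_shares": [
    0.087653,
    0.005357,
    0.443199,
    0.005357,
    0.050648,
    0.124077,
    0.065128,
    0.218581
   ],
   "concentration": 12.0,
   "mass_loc_kg": 1.8663,
   "mass_scale_kg": 0.3916,
   "age_mean": 40.2,
   "age_sd": 13.5,
   "bmi_mean": 25.6,
   "bmi_sd": 4.1,
   "female_fraction": 0.507,
   "income_mean": 3.1,
   "income_sd": 1.4,
   "tertiary_fraction": 0.422
  }
 }
}
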