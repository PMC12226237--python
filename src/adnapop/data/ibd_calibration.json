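{
 "calibration": {
  "band_means_cM": {
   "fifth_seventh": 111.5,
   "first": 3037.4,
   "second_fourth": 999.9
  },
  "band_sd_cM": {
   "fifth_seventh": 90.5,
   "first": 479.2,
   "second_fourth": 587.1
  },
  "replicates_per_relationship": 150,
  "seed": 2024
 },
 "first_degree_sum_cM": 2175.5,
 "min_detectable_cM": 16.0,
 "min_n_long": 2,
 "second_fourth_sum_cM": 263.0
}
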