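{
  "description": "Published counts from the comparative evaluation of food classification systems on the Thai packaged-food market (2015-2021 product launches). pairwise_2x2 cells are [n11, n12, n21, n22] with row = first-named system, column = second, in (unhealthy, healthy) order: n11 = both unhealthy, n22 = both healthy.",
  "n_complete_cases": 10486,
  "curation": {
    "n_input": 41145,
    "n_removed_no_nutrients": 18805,
    "n_removed_duplicates": 1250,
    "n_removed_excluded_category": 3676,
    "n_output": 17414
  },
  "doh_marketing_prohibited_shares_percent": {
    "auto_prohibited": 9.4,
    "group_a": 5.0,
    "group_b": 14.1,
    "group_c": 67.9
  },
  "systems_met_counts": {"0": 7100, "1": 2111, "2": 874, "3": 344, "4": 57},
  "pairwise_2x2": {
    "WHO_SEA|NOVA": [7961, 1358, 758, 409],
    "DOH|NOVA": [7998, 1446, 721, 321],
    "DOH|WHO_SEA": [8819, 625, 500, 542],
    "HCL|NOVA": [7889, 1455, 830, 312],
    "HCL|WHO_SEA": [8522, 822, 797, 345],
    "HCL|DOH": [8621, 723, 823, 319]
  }
}
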