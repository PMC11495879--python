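{
  "cell_area_m2": 0.25,
  "cover": {
    "2019": {
      "n_stands": 3,
      "percent_cover": 15.959999999999999,
      "scrub_area_m2": 99.75,
      "site_area_m2": 625.0,
      "stand_max_m2": 56.25,
      "stand_min_m2": 16.25
    },
    "2021": {
      "n_stands": 3,
      "percent_cover": 6.279999999999999,
      "scrub_area_m2": 39.25,
      "site_area_m2": 625.0,
      "stand_max_m2": 27.25,
      "stand_min_m2": 4.75
    }
  },
  "epochs": [
    "2019",
    "2021"
  ],
  "patch_areas_m2": {
    "east_scatter": 16.25,
    "gull_ridge": 27.25,
    "new_fringe": 4.75,
    "south_block": 56.25,
    "sycamore_clump": 7.25
  },
  "site_area_m2": 625.0,
  "transitions": {
    "2019->2021": {
      "GROUND->SCRUB": 19,
      "GROUND->TREES": 0,
      "SCRUB->GROUND": 290,
      "SCRUB->TREES": 0,
      "TREES->GROUND": 0,
      "TREES->SCRUB": 29
    }
  }
}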