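{
  "cell_area_m2": 0.25,
  "cover": {
    "2015": {
      "n_stands": 3,
      "percent_cover": 9.75,
      "scrub_area_m2": 87.75,
      "site_area_m2": 900.0,
      "stand_max_m2": 36.25,
      "stand_min_m2": 15.75
    },
    "2017": {
      "n_stands": 4,
      "percent_cover": 12.277777777777779,
      "scrub_area_m2": 110.5,
      "site_area_m2": 900.0,
      "stand_max_m2": 36.25,
      "stand_min_m2": 15.75
    },
    "2021": {
      "n_stands": 2,
      "percent_cover": 6.555555555555556,
      "scrub_area_m2": 59.0,
      "site_area_m2": 900.0,
      "stand_max_m2": 36.25,
      "stand_min_m2": 22.75
    }
  },
  "epochs": [
    "2015",
    "2017",
    "2021"
  ],
  "patch_areas_m2": {
    "bank_edge": 35.75,
    "beech_line": 31.25,
    "hawthorn_core": 36.25,
    "new_colony": 22.75,
    "old_thicket": 15.75
  },
  "site_area_m2": 900.0,
  "transitions": {
    "2015->2017": {
      "GROUND->SCRUB": 91,
      "GROUND->TREES": 0,
      "SCRUB->GROUND": 0,
      "SCRUB->TREES": 0,
      "TREES->GROUND": 0,
      "TREES->SCRUB": 0
    },
    "2015->2021": {
      "GROUND->SCRUB": 91,
      "GROUND->TREES": 0,
      "SCRUB->GROUND": 143,
      "SCRUB->TREES": 63,
      "TREES->GROUND": 0,
      "TREES->SCRUB": 0
    },
    "2017->2021": {
      "GROUND->SCRUB": 0,
      "GROUND->TREES": 0,
      "SCRUB->GROUND": 143,
      "SCRUB->TREES": 63,
      "TREES->GROUND": 0,
      "TREES->SCRUB": 0
    }
  }
}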