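{
  "_note": "Neonatal vancomycin dosing rules from seven published references. Rules are evaluated in order; the first matching rule applies. Ranges are half-open [lo, hi); null means unbounded. Ages: PMA/GA in weeks, PNA in days; SCR in umol/L; WT in kg.",
  "guidelines": {
    "neonatal_formulary_2015": {
      "label": "Neonatal Formulary (2015)",
      "rules": [
        {"pma": [null, 30], "dose_mg_per_kg": [20, 20], "interval_h": 24},
        {"pma": [30, 34], "dose_mg_per_kg": [20, 20], "interval_h": 18},
        {"pma": [34, 38], "dose_mg_per_kg": [20, 20], "interval_h": 12},
        {"pma": [38, 45], "dose_mg_per_kg": [15, 15], "interval_h": 8},
        {"pma": [45, null], "dose_mg_per_kg": [10, 10], "interval_h": 6}
      ]
    },
    "red_book_2015": {
      "label": "Red Book (2015)",
      "rules": [
        {"scr": [null, 61.9], "dose_mg_per_kg": [15, 15], "interval_h": 12},
        {"scr": [61.9, 79.6], "dose_mg_per_kg": [20, 20], "interval_h": 24},
        {"scr": [88.4, 106.1], "dose_mg_per_kg": [15, 15], "interval_h": 24},
        {"scr": [114.9, 141.5], "dose_mg_per_kg": [10, 10], "interval_h": 24},
        {"scr": [141.5, null], "dose_mg_per_kg": [15, 15], "interval_h": 48}
      ]
    },
    "pediatric_neonatal_dosage_handbook_2015": {
      "label": "Pediatric & Neonatal Dosage Handbook (2015-2016)",
      "rules": [
        {"ga": [null, 28.001], "scr": [null, 44.2], "dose_mg_per_kg": [15, 15], "interval_h": 12},
        {"ga": [null, 28.001], "scr": [44.2, 61.9], "dose_mg_per_kg": [20, 20], "interval_h": 24},
        {"ga": [null, 28.001], "scr": [70.7, 97.3], "dose_mg_per_kg": [15, 15], "interval_h": 24},
        {"ga": [null, 28.001], "scr": [97.3, 123.8], "dose_mg_per_kg": [10, 10], "interval_h": 24},
        {"ga": [null, 28.001], "scr": [123.8, null], "dose_mg_per_kg": [15, 15], "interval_h": 48},
        {"ga": [28.001, null], "scr": [null, 61.9], "dose_mg_per_kg": [15, 15], "interval_h": 12},
        {"ga": [28.001, null], "scr": [61.9, 79.6], "dose_mg_per_kg": [20, 20], "interval_h": 24},
        {"ga": [28.001, null], "scr": [88.4, 106.1], "dose_mg_per_kg": [15, 15], "interval_h": 24},
        {"ga": [28.001, null], "scr": [114.9, 141.5], "dose_mg_per_kg": [10, 10], "interval_h": 24},
        {"ga": [28.001, null], "scr": [141.5, null], "dose_mg_per_kg": [15, 15], "interval_h": 48},
        {"pna": [null, 7], "wt": [null, 1.2], "dose_mg_per_kg": [15, 15], "interval_h": 24},
        {"pna": [null, 7], "wt": [1.2, 2.0], "dose_mg_per_kg": [10, 15], "interval_h": 15},
        {"pna": [null, 7], "wt": [2.0, null], "dose_mg_per_kg": [10, 15], "interval_h": 10},
        {"pna": [7, null], "wt": [null, 1.2], "dose_mg_per_kg": [15, 15], "interval_h": 24},
        {"pna": [7, null], "wt": [1.2, 2.0], "dose_mg_per_kg": [10, 15], "interval_h": 10},
        {"pna": [7, null], "wt": [2.0, null], "dose_mg_per_kg": [15, 15], "interval_h": 7}
      ]
    },
    "bnf_children_2016": {
      "label": "BNF for Children (2016-2017)",
      "rules": [
        {"pma": [null, 29], "dose_mg_per_kg": [15, 15], "interval_h": 24},
        {"pma": [29, 35.001], "dose_mg_per_kg": [15, 15], "interval_h": 12},
        {"pma": [35.001, null], "dose_mg_per_kg": [15, 15], "interval_h": 8}
      ]
    },
    "blue_book_2016": {
      "label": "Blue Book (2016)",
      "rules": [
        {"pma": [null, 29], "dose_mg_per_kg": [15, 15], "interval_h": 24},
        {"pma": [29, 35.001], "dose_mg_per_kg": [15, 15], "interval_h": 12},
        {"pma": [35.001, null], "dose_mg_per_kg": [15, 15], "interval_h": 8}
      ]
    },
    "neofax_2017": {
      "label": "Neofax (2017)",
      "rules": [
        {"pma": [null, 29.001], "pna": [null, 14.001], "dose_mg_per_kg": [10, 15], "interval_h": 18},
        {"pma": [null, 29.001], "pna": [14.001, null], "dose_mg_per_kg": [10, 15], "interval_h": 12},
        {"pma": [29.001, 36.001], "pna": [null, 14.001], "dose_mg_per_kg": [10, 15], "interval_h": 12},
        {"pma": [29.001, 36.001], "pna": [14.001, null], "dose_mg_per_kg": [10, 15], "interval_h": 8},
        {"pma": [36.001, 44.001], "pna": [null, 14.001], "dose_mg_per_kg": [10, 15], "interval_h": 12},
        {"pma": [36.001, 44.001], "pna": [14.001, null], "dose_mg_per_kg": [10, 15], "interval_h": 8},
        {"pma": [44.001, null], "dose_mg_per_kg": [10, 15], "interval_h": 6}
      ]
    },
    "fda_label_2017": {
      "label": "FDA labeled dosage (2017)",
      "rules": [
        {"pna": [null, 7.001], "dose_mg_per_kg": [10, 10], "interval_h": 12},
        {"pna": [7.001, 30.001], "dose_mg_per_kg": [10, 10], "interval_h": 8}
      ]
    }
  }
}
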