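{
  "description": "Baseline configuration: bariatric surgery vs. conventional medical care for morbidly obese type-2 diabetes in Thailand, costs in 2017 THB. Year-1 outcome probabilities from the KCMH surgical cohort (surgery arm) and published trial data (no-surgery arm). The years-2+ dynamics are an explicit modelling assumption: states persist except a 5%/year remission-to-improved relapse and a flat 0.0001/year death probability from every alive state. Parameter ranges: published cost ranges where available; probabilities and utilities +/-10% truncated to [0,1]; discount rate 0-6%.",
  "arm_probabilities": {
    "surgery": {
      "remission": 0.8356,
      "improved": 0.0411,
      "persistent": 0.0099,
      "uncontrolled": 0.1233,
      "dead": 0.0001
    },
    "no_surgery": {
      "remission": 0.0001,
      "improved": 0.23,
      "persistent": 0.17,
      "uncontrolled": 0.5998,
      "dead": 0.0001
    }
  },
  "costs": {
    "surgery_one_time": 150000.0,
    "medication": {
      "metformin": 538.6,
      "sulfonylurea": 162.0,
      "thiazolidinedione": 12840.0,
      "alpha_glucosidase_inhibitor": 1155.6,
      "insulin": 3480.0
    },
    "supplementation": 396.0,
    "complication_management": 15326.4,
    "persistent_second_agent": "sulfonylurea",
    "uncontrolled_regimen": ["metformin", "sulfonylurea", "insulin"]
  },
  "utilities": {
    "remission": 0.83,
    "improved": 0.8,
    "persistent": 0.78,
    "uncontrolled": 0.75,
    "dead": 0.0
  },
  "transition": {
    "surgery": {
      "relapse_probability": 0.05,
      "death_probability": 0.0001
    },
    "no_surgery": {
      "relapse_probability": 0.05,
      "death_probability": 0.0001
    }
  },
  "discount_rate": 0.03,
  "effect_discount_rate": null,
  "horizon_years": 50,
  "wtp_band": [150000.0, 200000.0],
  "cpi_base_year": 2017,
  "half_cycle_correction": false,
  "parameter_ranges": {
    "costs.surgery_one_time": [126200.0, 157500.0],
    "costs.medication.metformin": [269.0, 3331.0],
    "costs.medication.sulfonylurea": [154.0, 168.0],
    "costs.medication.thiazolidinedione": [6420.0, 25680.0],
    "costs.medication.alpha_glucosidase_inhibitor": [577.8, 1964.4],
    "costs.medication.insulin": [2040.0, 7680.0],
    "costs.supplementation": [367.2, 568.8],
    "costs.complication_management": [3672.0, 25895.0],
    "arm_probabilities.surgery.remission": [0.75204, 0.91916],
    "arm_probabilities.no_surgery.uncontrolled": [0.53982, 0.65978],
    "utilities.remission": [0.747, 0.913],
    "utilities.improved": [0.72, 0.88],
    "utilities.persistent": [0.702, 0.858],
    "utilities.uncontrolled": [0.675, 0.825],
    "discount_rate": [0.0, 0.06],
    "transition.surgery.relapse_probability": [0.0, 0.1]
  }
}
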