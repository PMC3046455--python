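{
  "studies": [
    {"label": "ABCFS", "n_cases": 1239, "n_controls": 610, "population_based": true},
    {"label": "BBCC", "n_cases": 1200, "n_controls": 806, "population_based": false},
    {"label": "BBCS", "n_cases": 1338, "n_controls": 1242, "population_based": false},
    {"label": "CGPS", "n_cases": 1450, "n_controls": 6555, "population_based": true},
    {"label": "CNIO-BCS", "n_cases": 351, "n_controls": 649, "population_based": false},
    {"label": "GENICA", "n_cases": 917, "n_controls": 967, "population_based": true},
    {"label": "GESBC", "n_cases": 573, "n_controls": 859, "population_based": true},
    {"label": "KBCP", "n_cases": 430, "n_controls": 388, "population_based": false},
    {"label": "kConFab-AOCS", "n_cases": 323, "n_controls": 171, "population_based": false},
    {"label": "LMBC", "n_cases": 818, "n_controls": 804, "population_based": false},
    {"label": "MARIE", "n_cases": 2573, "n_controls": 5294, "population_based": true},
    {"label": "MCBCS", "n_cases": 1049, "n_controls": 1045, "population_based": false},
    {"label": "MCCS", "n_cases": 682, "n_controls": 749, "population_based": true},
    {"label": "NC-BCFR", "n_cases": 266, "n_controls": 154, "population_based": true},
    {"label": "OFBCR", "n_cases": 982, "n_controls": 328, "population_based": true},
    {"label": "PBCS", "n_cases": 1937, "n_controls": 2322, "population_based": true},
    {"label": "SASBAC", "n_cases": 1408, "n_controls": 1400, "population_based": true},
    {"label": "SBCS", "n_cases": 970, "n_controls": 1088, "population_based": false},
    {"label": "SEARCH", "n_cases": 6352, "n_controls": 5282, "population_based": false},
    {"label": "UCIBCS", "n_cases": 795, "n_controls": 465, "population_based": true},
    {"label": "USRT", "n_cases": 696, "n_controls": 1030, "population_based": false}
  ],
  "catalog": "default",
  "main_effect_ors": {
    "menarche": 0.96,
    "ever_birth": 0.84,
    "n_births": 0.89,
    "age_first_birth": 1.0136,
    "bmi_lt55": 0.97,
    "bmi_ge55": 1.0,
    "age": 1.02
  },
  "interaction_ors": [
    {"snp": "11p15-rs3817198", "factor": "n_births", "or": 1.05}
  ],
  "missingness": {
    "menarche_age": 0.2,
    "parous": 0.08,
    "n_live_births": 0.1,
    "age_first_birth": 0.2,
    "bmi": 0.3,
    "dosage": 0.12
  },
  "subtype": {"p_er_pos": 0.75, "p_pr_pos": 0.70},
  "prevalence_target": 0.125,
  "prevalence_band": [0.05, 0.2]
}
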