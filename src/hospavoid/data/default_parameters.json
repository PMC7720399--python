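{
  "currency_year": 2018,
  "equipment_life_years": 7,
  "parameters": [
    {"name": "p_death", "arm": "", "mean": 0.0011, "sd": 0.0001, "family": "beta", "source": "study data, all residents"},
    {"name": "p_subacute_onset", "arm": "intervention", "mean": 0.003, "sd": 0.007, "family": "beta", "source": "study data"},
    {"name": "p_treat_in_facility", "arm": "intervention", "mean": 0.670, "sd": 0.388, "family": "beta", "source": "study data"},
    {"name": "p_admit_from_subacute", "arm": "intervention", "mean": 0.722, "sd": 0.288, "family": "beta", "source": "study data"},
    {"name": "p_discharge", "arm": "intervention", "mean": 0.283, "sd": 0.150, "family": "beta", "source": "study data"},
    {"name": "p_admit_direct", "arm": "usual_care", "mean": 0.001, "sd": 0.004, "family": "beta", "source": "study data"},
    {"name": "p_discharge", "arm": "usual_care", "mean": 0.151, "sd": 0.072, "family": "beta", "source": "study data"},
    {"name": "cost_racf_bed_day", "arm": "", "mean": 194, "sd": 76, "family": "normal", "source": "national fee schedule"},
    {"name": "cost_ambulance", "arm": "", "mean": 649, "sd": 254, "family": "normal", "source": "published tariff"},
    {"name": "cost_hospital_bed_day", "arm": "", "mean": 1807, "sd": 1028, "family": "gamma", "source": "published estimate, inflated to 2018 AUD"},
    {"name": "equipment:bladder_scanner", "arm": "", "mean": 1714, "sd": 672, "family": "normal", "source": "study data, annualised over 7 years"},
    {"name": "equipment:ecg_machine", "arm": "", "mean": 351, "sd": 138, "family": "normal", "source": "study data, annualised over 7 years"},
    {"name": "equipment:vital_signs_monitor", "arm": "", "mean": 277, "sd": 109, "family": "normal", "source": "study data, annualised over 7 years"},
    {"name": "utility_racf", "arm": "", "mean": 0.514, "sd": 0.252, "family": "beta", "source": "published estimate"},
    {"name": "utility_hospital", "arm": "", "mean": 0.44, "sd": 0.4, "family": "beta", "source": "published estimate"}
  ]
}
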