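{
  "scenarios": {
    "diagnosis": {
      "label": "diagnosis",
      "horizon_years": 10,
      "patients_per_day": {"kind": "linear", "start_value": 20, "end_value": 65},
      "hospitals": {"kind": "linear", "start_value": 20, "end_value": 38},
      "saved_minutes": {"kind": "linear", "start_value": 10, "end_value": 14},
      "unit_cost_year1": 500,
      "cost_growth_rate": 0.1,
      "days_per_year": 365
    },
    "treatment": {
      "label": "treatment",
      "horizon_years": 10,
      "patients_per_day": {"kind": "linear", "start_value": 20, "end_value": 55},
      "hospitals": {"kind": "linear", "start_value": 15, "end_value": 21},
      "saved_minutes": {"kind": "linear", "start_value": 65, "end_value": 134},
      "unit_cost_year1": 1000,
      "cost_growth_rate": 0.1,
      "days_per_year": 365
    }
  },
  "output_dir": ".",
  "report_rounding": 2
}
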