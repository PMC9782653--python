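{
  "version": "2022.1",
  "limits_ug_per_day": {
    "organophosphate_carbamate": 18,
    "genotoxic": {
      "gt_10_years_lifetime": 1.5,
      "1_to_10_years": 10,
      "1_to_12_months": 20,
      "lt_1_month": 120
    },
    "cramer_class_1": 865,
    "cramer_class_2_or_3": 145,
    "oasis_base_surface_narcotic": 22.39,
    "oasis_reactive": 4.286
  }
}
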