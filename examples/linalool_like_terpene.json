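{
  "name": "linalool-like-terpene",
  "cas_number": "78-70-6",
  "purity_fraction": 0.97,
  "native_to_cannabis": true,
  "gras_or_food_use": true,
  "cramer_class": "1",
  "developmental_data_available": true,
  "evidence_tier": "other_route_guideline",
  "pods": [
    {
      "value": 250,
      "units": "mg_per_kg_bw_per_day",
      "pod_type": "NOAEL",
      "route": "oral",
      "species": "animal",
      "duration_class": "subchronic",
      "days_per_week": 7,
      "test_article_purity": 1.0,
      "endpoint_scope": "systemic"
    }
  ]
}
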