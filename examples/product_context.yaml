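# Finished-product context: an adult-use (age-gated) THC concentrate
product_thc_concentration: 850   # mg/g
age_gated: true
intended_exposure_duration: gt_10_years_lifetime
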