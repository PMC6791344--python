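{
  "_comment": "January-2019 USD list prices for the five library-prep strategies. itru_buy_in: indexed universal primer aliquots; oligo_buy_in: locus-specific / fusion oligo synthesis; fixed_per_sample: per-library reagents; variable_per_pool: one pooled second-round (limited-cycle) reaction per pool, null for methods that run a second-round PCR per sample.",
  "1": {"itru_buy_in": 500.0, "oligo_buy_in": 103.0, "fixed_per_sample": 18.86, "variable_per_pool": null, "pooled_itru": false},
  "2": {"itru_buy_in": 500.0, "oligo_buy_in": 460.0, "fixed_per_sample": 3.12, "variable_per_pool": 4.07, "pooled_itru": true},
  "3": {"itru_buy_in": 500.0, "oligo_buy_in": 290.0, "fixed_per_sample": 1.39, "variable_per_pool": 17.52, "pooled_itru": true},
  "4": {"itru_buy_in": 500.0, "oligo_buy_in": 40.0, "fixed_per_sample": 4.44, "variable_per_pool": null, "pooled_itru": false},
  "5": {"itru_buy_in": 500.0, "oligo_buy_in": 445.0, "fixed_per_sample": 1.39, "variable_per_pool": 4.07, "pooled_itru": true}
}
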