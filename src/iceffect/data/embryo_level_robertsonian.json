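{
  "description": "Embryo-level abnormality counts for the cleavage-stage Robertsonian comparison. A sample counts as abnormal only if it carries at least one error on a chromosome not involved in the matched patient's rearrangement. The published aggregate gives counts for the eligible control groups but only the proportion for the carrier arm.",
  "control": {"abnormal_samples": 1185, "total_samples": 1861},
  "carrier": {"abnormal_proportion": 0.6981}
}
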