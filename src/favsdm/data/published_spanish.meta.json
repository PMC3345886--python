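{
  "label": "Spanish model",
  "intercept": -44.63,
  "n1": null,
  "n0": null,
  "notes": "Published Iberian favourability model for Galemys pyrenaicus, transferred to the French range. Coefficients, constant and order-of-inclusion ranks stored exactly as printed; training n1/n0 were not published, so the favourability transform needs an explicit prevalence."
}
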