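{
  "label": "French model without latitude",
  "intercept": 481.0,
  "n1": null,
  "n0": null,
  "notes": "French-range refit using environmental variables only. The constant was printed parenthesized as '(481)' with ambiguous sign/format; the printed positive value is stored verbatim. Training n1/n0 were not published."
}
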