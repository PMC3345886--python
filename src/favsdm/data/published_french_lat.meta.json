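{
  "label": "French model with latitude",
  "intercept": 496.9,
  "n1": null,
  "n0": null,
  "notes": "French-range refit including latitude; the best-performing 5-variable model. Ranks stored as printed: Prec and Lati both carry rank (3) and no rank (4) appears, an inconsistency in the source table that is flagged, not repaired. The constant was printed parenthesized as '(496.9)'; the printed positive value is stored verbatim. 'Alti250' is kept as printed (altitude at a different support than 'Alti'). Training n1/n0 were not published."
}
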