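# Demo pipeline configuration: a 50x50 two-region scenario with a shifted
# target precipitation range, stepwise fitting, evaluation, transference
# and favourability maps. Run with:
#   favsdm run --config demo_config.yaml --seed 1 --out runs/demo
seed: 1
stages: [simulate, fit, evaluate, transfer, compare, map]
scenario:
  n_rows: 50
  n_cols: 50
  shifted: true
fit:
  method: stepwise
  candidates: [Prec, Alti, SRad, DPre, Lati]
  entry_alpha: 0.05
threshold: 0.5
prevalence_source: training
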