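"""End-to-end orchestration: simulate -> fit -> evaluate -> transfer -> map.

A pipeline run is fully determined by a configuration mapping (usually
loaded from YAML) and a master seed: every stochastic stage derives its
seed from the master, outputs are written with stable formatting, and a
``manifest.json`` records a SHA-256 checksum per artifact so re-runs can
be verified byte-for-byte.

Config schema (all keys optional unless noted)::

    seed: 1                     # master seed (int, required unless passed)
    stages: [simulate, fit, evaluate, transfer, compare, map]
    scenario:
      n_rows: 40
      n_cols: 40
      shifted: true             # shift target precipitation range
      extra_variables: {}       # e.g. {HJul: [30, 90]} adds more layers
    fit:
      method: stepwise          # stepwise | glm
      candidates: [Prec, Alti, SRad, DPre, Lati]
      entry_alpha: 0.05
    model: path/to/model.csv    # used instead of fitting when 'fit' is off
    threshold: 0.5              # number | prevalence | max_tss
    prevalence_source: training # training | target
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from .errors import ConfigError, InputError
from .evaluation import evaluate_model, write_report_json, write_reports_csv
from .glm import (fit_logistic, forward_stepwise, favourability_surface,
                  read_coefficients_csv, write_coefficients_csv)
from .grids import (read_detections_csv, read_grid_dir, write_ascii_grid,
                    write_detections_csv, write_grid_dir)
from .synthetic import default_scenario_truth, generate_two_region_scenario
from .transfer import compare_models, transfer_model

log = logging.getLogger("favsdm")

ALL_STAGES = ("simulate", "fit", "evaluate", "transfer", "compare", "map")

_DEFAULTS = {
    "stages": list(ALL_STAGES),
    "scenario": {"n_rows": 40, "n_cols": 40, "shifted": True,
                 "extra_variables": {}},
    "fit": {"method": "stepwise",
            "candidates": ["Prec", "Alti", "SRad", "DPre", "Lati"],
            "entry_alpha": 0.05},
    "threshold": 0.5,
    "prevalence_source": "training",
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise InputError(f"cannot parse {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError("config: top level must be a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Merge with defaults and validate; errors name the offending key."""
    out = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, val in cfg.items():
        if key not in (*_DEFAULTS, "seed", "model"):
            raise ConfigError(f"config: unknown key {key!r}")
        if isinstance(val, dict) and key in out and isinstance(out[key], dict):
            for sub, sval in val.items():
                if sub not in out[key]:
                    raise ConfigError(f"config: unknown key {key}.{sub!r}")
                out[key][sub] = sval
        else:
            out[key] = val
    if "seed" in out and not isinstance(out["seed"], int):
        raise ConfigError("config: 'seed' must be an integer")
    for stage in out["stages"]:
        if stage not in ALL_STAGES:
            raise ConfigError(f"config: 'stages' contains unknown stage {stage!r}")
    sc = out["scenario"]
    for key in ("n_rows", "n_cols"):
        if not (isinstance(sc[key], int) and sc[key] >= 1):
            raise ConfigError(f"config: 'scenario.{key}' must be a positive integer")
    extra = sc["extra_variables"]
    if not isinstance(extra, dict):
        raise ConfigError("config: 'scenario.extra_variables' must be a "
                          "mapping of variable code to [min, max]")
    for var, pair in extra.items():
        if (not isinstance(pair, (list, tuple)) or len(pair) != 2
                or not pair[0] < pair[1]):
            raise ConfigError(
                f"config: 'scenario.extra_variables.{var}' must be "
                "[min, max] with min < max")
    if out["fit"]["method"] not in ("stepwise", "glm"):
        raise ConfigError("config: 'fit.method' must be 'stepwise' or 'glm'")
    thr = out["threshold"]
    if not (isinstance(thr, (int, float)) or thr in ("prevalence", "max_tss")):
        raise ConfigError("config: 'threshold' must be a number, "
                          "'prevalence' or 'max_tss'")
    if out["prevalence_source"] not in ("training", "target"):
        raise ConfigError("config: 'prevalence_source' must be "
                          "'training' or 'target'")
    if "fit" not in out["stages"] and "model" not in out:
        needs_model = {"evaluate", "transfer", "compare", "map"}
        if needs_model & set(out["stages"]):
            raise ConfigError("config: 'model' path required when the 'fit' "
                              "stage is disabled")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the configured stages, write all artifacts, return the manifest.

    ``seed`` overrides ``config['seed']``. The manifest maps each artifact's
    path (relative to ``out_dir``) to its SHA-256 checksum and is also
    written to ``<out_dir>/manifest.json``.
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if "seed" not in cfg:
        raise ConfigError("config: 'seed' is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    artifacts: list[Path] = []

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("pipeline start: seed=%d stages=%s", cfg["seed"], stages)

        train = target = None
        if "simulate" in stages:
            sc = cfg["scenario"]
            truth = default_scenario_truth(cfg["seed"], shifted=sc["shifted"])
            for var, pair in sc["extra_variables"].items():
                for region_ranges in truth.covariate_ranges.values():
                    region_ranges[var] = (float(pair[0]), float(pair[1]))
            train, target = generate_two_region_scenario(
                truth, sc["n_rows"], sc["n_cols"])
            for name, (grid, det) in (("train", train), ("target", target)):
                gdir = out_dir / f"{name}_grid"
                artifacts += write_grid_dir(gdir, grid)
                obs = out_dir / f"{name}_observations.csv"
                write_detections_csv(obs, det)
                artifacts.append(obs)
                log.info("%s region: %dx%d cells, n1=%d n0=%d", name,
                         grid.n_rows, grid.n_cols, det.n1, det.n0)

        model = None
        if "fit" in stages:
            if train is None:
                raise ConfigError("config: 'fit' stage requires 'simulate' "
                                  "(or supply 'model' and disable 'fit')")
            fc = cfg["fit"]
            grid, det = train
            if fc["method"] == "stepwise":
                model = forward_stepwise(grid, det, fc["candidates"],
                                         entry_alpha=fc["entry_alpha"],
                                         label="stepwise model")
                log.info("stepwise selected %s (entry_alpha=%g)",
                         model.inclusion_order, fc["entry_alpha"])
            else:
                model = fit_logistic(grid, det, fc["candidates"],
                                     label="full GLM")
            log.info("fitted model: n1=%d n0=%d llf=%.4f", model.n1,
                     model.n0, model.log_likelihood)
            mpath = out_dir / "model.csv"
            write_coefficients_csv(mpath, model)
            artifacts += [mpath, mpath.with_suffix(".meta.json")]
        elif "model" in cfg:
            model = read_coefficients_csv(cfg["model"])
            log.info("loaded model %r from %s", model.label, cfg["model"])

        thr = cfg["threshold"]
        psrc = cfg["prevalence_source"]
        if "evaluate" in stages:
            grid, det = _require(train, "evaluate", "simulate")
            report = evaluate_model(model, grid, det, thr, psrc)
            log.info("evaluate (training region): threshold=%r "
                     "prevalence_source=%s auc=%.4f tss=%.4f", thr, psrc,
                     report.auc, report.tss)
            rpath = out_dir / "report_train.json"
            write_report_json(rpath, report)
            artifacts.append(rpath)

        if "transfer" in stages:
            tgrid, tdet = _require(target, "transfer", "simulate")
            res = transfer_model(model, tgrid, tdet, psrc, thr)
            log.info("transfer: auc=%.4f coverage=%s", res.report.auc,
                     {k: round(v, 3) for k, v in res.coverage.items()})
            rpath = out_dir / "report_transfer.json"
            write_report_json(rpath, res.report)
            artifacts.append(rpath)
            cpath = out_dir / "transfer_coverage.json"
            with open(cpath, "w") as fh:
                json.dump(res.coverage, fh, indent=2)
                fh.write("\n")
            artifacts.append(cpath)
            spath = out_dir / "favourability_target.asc"
            write_ascii_grid(spath, res.surface.values,
                             cell_size=res.surface.cell_size,
                             origin=res.surface.origin)
            artifacts.append(spath)

        if "compare" in stages:
            grid, det = _require(train, "compare", "simulate")
            full = fit_logistic(grid, det, cfg["fit"]["candidates"],
                                label="full GLM")
            table = compare_models([model, full], grid, det, thr, psrc)
            cpath = out_dir / "comparison.csv"
            table.to_csv(cpath, index=False)
            artifacts.append(cpath)
            log.info("compare: %d models scored", len(table))

        if "map" in stages:
            grid, _det = _require(train, "map", "simulate")
            surface = favourability_surface(model, grid, psrc,
                                            target_det=_det)
            spath = out_dir / "favourability_train.asc"
            write_ascii_grid(spath, surface.values,
                             cell_size=surface.cell_size,
                             origin=surface.origin)
            artifacts.append(spath)

        manifest = {str(p.relative_to(out_dir)): _sha256(p)
                    for p in sorted(set(artifacts))}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("pipeline done: %d artifacts", len(manifest))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()


def _require(pair, stage: str, needs: str):
    if pair is None:
        raise ConfigError(
            f"config: stage {stage!r} requires stage {needs!r} in this run"
        )
    return pair
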