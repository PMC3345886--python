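"""Discrimination indices for presence/absence predictions.

Threshold-dependent indices (computed from a confusion matrix at a stated
cut-off on the score surface):

==============  ==========================================================
sensitivity     TP / (TP + FN) — presences correctly predicted
specificity     TN / (TN + FP) — absences correctly predicted
PCC (= OA)      (TP + TN) / N — percent correctly classified
PPP             TP / (TP + FP) — predicted presences that are correct
NPP             TN / (TN + FN) — predicted absences that are correct
TSS             sensitivity + specificity - 1 (0 random, 1 perfect)
Kappa           chance-corrected agreement
==============  ==========================================================

TSS, unlike Kappa and PCC, does not depend on prevalence, which is what
makes it the index of choice when comparing models across surveys with
different presence/absence ratios. AUC (the probability that a randomly
chosen presence outscores a randomly chosen absence) is the
threshold-independent companion, computed here by the Mann-Whitney rank
statistic with the standard half-credit tie correction.

Indices whose denominator is zero are *undefined* and reported as NaN,
never as 0 or 1 — degenerate predictions must not look perfect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError
from .grids import DetectionGrid, EnvironmentalGrid

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "confusion_matrix",
    "threshold_indices",
    "auc",
    "evaluate_model",
    "resolve_threshold",
]


@dataclass
class ConfusionMatrix:
    """Counts of a binary classification at a stated threshold.

    Predicted present iff ``score >= threshold`` (ties side with presence).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    score_kind: str = "favourability"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceReport:
    """The full index suite for one model on one set of observations.

    Undefined indices are NaN; ``undefined`` lists their names.
    """

    sensitivity: float
    specificity: float
    pcc: float
    ppp: float
    npp: float
    tss: float
    kappa: float
    auc: float
    confusion: ConfusionMatrix
    model_label: str = ""
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(v):
            return None if (isinstance(v, float) and math.isnan(v)) else v
        return {
            "model_label": self.model_label,
            "indices": {k: clean(getattr(self, k)) for k in (
                "sensitivity", "specificity", "pcc", "ppp", "npp",
                "tss", "kappa", "auc")},
            "undefined": list(self.undefined),
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "tn": self.confusion.tn, "fn": self.confusion.fn,
                "threshold": self.confusion.threshold,
                "score_kind": self.confusion.score_kind,
            },
        }


def _paired(scores, det: DetectionGrid) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(getattr(scores, "values", scores), dtype=float)
    if scores.shape != det.shape:
        raise InputError(
            f"scores shape {scores.shape} != detections shape {det.shape}"
        )
    keep = det.observed_mask() & np.isfinite(scores)
    if not keep.any():
        raise InputError("no cells with both a score and an outcome")
    return scores[keep], det.outcomes[keep]


def confusion_matrix(scores, det: DetectionGrid, threshold: float,
                     score_kind: str = "favourability") -> ConfusionMatrix:
    """Tally TP/FP/TN/FN over surveyed cells at the given threshold."""
    if not math.isfinite(threshold):
        raise InputError(f"threshold must be finite, got {threshold}")
    s, y = _paired(scores, det)
    pred = s >= threshold
    return ConfusionMatrix(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
        threshold=float(threshold),
        score_kind=score_kind,
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def threshold_indices(cm: ConfusionMatrix) -> dict[str, float]:
    """All threshold-dependent indices from a confusion matrix.

    Returns a dict with keys sensitivity, specificity, pcc, ppp, npp,
    tss, kappa; undefined entries are NaN.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    pcc = _ratio(tp + tn, cm.total)
    ppp = _ratio(tp, tp + fp)
    npp = _ratio(tn, tn + fn)
    # TSS = sens + spec - 1 reduces to one exact integer ratio; computing it
    # as a single division keeps the result correctly rounded
    tss = _ratio(tp * tn - fn * fp, (tp + fn) * (tn + fp)) \
        if (tp + fn) > 0 and (tn + fp) > 0 else float("nan")
    # Kappa likewise: (po - pe)/(1 - pe) in lowest integer terms
    kden = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    kappa = _ratio(2 * (tp * tn - fn * fp), kden)
    return {"sensitivity": sens, "specificity": spec, "pcc": pcc,
            "ppp": ppp, "npp": npp, "tss": tss, "kappa": kappa}


def auc(scores, det: DetectionGrid) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    ``AUC = (R1 - n1(n1+1)/2) / (n1 n0)`` where R1 is the rank sum of the
    presence scores with midranks on ties — identical to counting, over all
    presence/absence pairs, wins plus half-credit ties.
    """
    s, y = _paired(scores, det)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InputError(
            f"AUC needs both classes (n1={n1}, n0={n0})"
        )
    ranks = rankdata(s)  # average ranks on ties
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def resolve_threshold(scores, det: DetectionGrid, policy) -> float:
    """Turn a threshold policy into a numeric cut-off.

    Policies:
      * a number — used as-is (default elsewhere: 0.5, which on the
        favourability scale classifies cells more favourable than the
        training average as 'present');
      * ``"prevalence"`` — the observed prevalence of ``det`` (the natural
        cut-off for raw probabilities);
      * ``"max_tss"`` — the observed score that maximizes TSS (ties broken
        toward the lowest such score).
    """
    if isinstance(policy, (int, float)) and not isinstance(policy, bool):
        return float(policy)
    if policy == "prevalence":
        return det.prevalence
    if policy == "max_tss":
        s, y = _paired(scores, det)
        best_t, best_tss = None, -np.inf
        for t in np.unique(s):
            pred = s >= t
            tp = (pred & (y == 1)).sum()
            fn = ((~pred) & (y == 1)).sum()
            tn = ((~pred) & (y == 0)).sum()
            fp = (pred & (y == 0)).sum()
            if tp + fn == 0 or tn + fp == 0:
                continue
            tss = tp / (tp + fn) + tn / (tn + fp) - 1.0
            if tss > best_tss:
                best_t, best_tss = float(t), tss
        if best_t is None:
            raise InputError("max_tss threshold undefined (single-class data)")
        return best_t
    raise InputError(
        f"unknown threshold policy {policy!r} "
        "(expected a number, 'prevalence' or 'max_tss')"
    )


def evaluate_scores(scores, det: DetectionGrid, threshold_policy=0.5,
                    model_label: str = "",
                    score_kind: str = "favourability") -> PerformanceReport:
    """Full report (threshold indices + AUC) for an arbitrary score surface."""
    thr = resolve_threshold(scores, det, threshold_policy)
    cm = confusion_matrix(scores, det, thr, score_kind=score_kind)
    idx = threshold_indices(cm)
    undefined = [k for k, v in idx.items() if isinstance(v, float) and math.isnan(v)]
    return PerformanceReport(
        sensitivity=idx["sensitivity"], specificity=idx["specificity"],
        pcc=idx["pcc"], ppp=idx["ppp"], npp=idx["npp"], tss=idx["tss"],
        kappa=idx["kappa"], auc=auc(scores, det), confusion=cm,
        model_label=model_label, undefined=undefined,
    )


def evaluate_model(coefs, grid: EnvironmentalGrid, det: DetectionGrid,
                   threshold_policy=0.5,
                   prevalence_source: str = "training") -> PerformanceReport:
    """Build the model's favourability surface and score it against ``det``."""
    from .glm import favourability_surface
    surface = favourability_surface(coefs, grid, prevalence_source,
                                    target_det=det)
    return evaluate_scores(surface.values, det, threshold_policy,
                           model_label=coefs.label)


# ---------------------------------------------------------------------------
# Report IO
# ---------------------------------------------------------------------------

def write_report_json(path: str | Path, report: PerformanceReport) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def write_reports_csv(path: str | Path,
                      reports: list[PerformanceReport]) -> None:
    rows = []
    for r in reports:
        d = r.to_dict()
        row = {"model_label": d["model_label"], **d["indices"],
               **{k: d["confusion"][k] for k in ("tp", "fp", "tn", "fn",
                                                 "threshold")}}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_report_json(path: str | Path) -> PerformanceReport:
    with open(path) as fh:
        d = json.load(fh)
    idx = {k: (float("nan") if v is None else v)
           for k, v in d["indices"].items()}
    c = d["confusion"]
    cm = ConfusionMatrix(tp=c["tp"], fp=c["fp"], tn=c["tn"], fn=c["fn"],
                         threshold=c["threshold"],
                         score_kind=c.get("score_kind", "favourability"))
    return PerformanceReport(confusion=cm, model_label=d.get("model_label", ""),
                             undefined=d.get("undefined", []), **idx)
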