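"""Logistic GLM fitting and the prevalence-corrected favourability transform.

A presence/absence logistic model returns a probability P whose scale is
tied to the sample's prevalence: the same environmental conditions yield a
higher P in a dataset with more presences. The *favourability* transform
removes that dependence by dividing the predicted odds by the sample's
presence/absence ratio::

    F = (P / (1 - P)) / (n1/n0 + P / (1 - P)) = e^y / (n1/n0 + e^y)

where ``y`` is the linear predictor and ``n1``/``n0`` are the training
presences/absences. F is 0.5 exactly where P equals the training
prevalence ``n1/(n1+n0)``, so F > 0.5 always means "conditions more
favourable than the sample average", regardless of how common the species
is in the data. That makes favourability surfaces comparable across
datasets, regions and species with different prevalences — the property
that justifies transferring a fitted model to a new region.

Model fitting is ordinary maximum-likelihood logistic regression
(statsmodels IRLS/Newton under the hood). Covariates enter unstandardized
— coefficients are reported in natural units (per mm, per degC, ...) — but
are standardized internally for conditioning and back-transformed, together
with their covariance, before reporting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InputError, SeparationWarning
from .grids import DetectionGrid, EnvironmentalGrid

__all__ = [
    "CoefficientSet",
    "FavourabilitySurface",
    "linear_predictor",
    "favourability",
    "fit_logistic",
    "forward_stepwise",
    "favourability_surface",
    "read_coefficients_csv",
    "write_coefficients_csv",
]

#: probabilities are clipped into [EPS, 1-EPS] before forming odds
EPS = 1e-12


@dataclass
class CoefficientSet:
    """A fitted (or published) logistic model: the unit of transference.

    Attributes
    ----------
    intercept
        Constant term on the logit scale.
    coefficients
        Variable code -> coefficient, in the variable's natural units.
    inclusion_order
        Variable code -> 1-based rank at which the variable entered during
        stepwise selection, when known. Stored exactly as reported by the
        selection (or as printed, for published models), even if the ranks
        are not a clean permutation; see :meth:`rank_warnings`.
    n1, n0
        Training presences / absences, required by the favourability
        transform with ``prevalence_source="training"``.
    label
        Free-text model name.
    se, intercept_se
        Estimated standard errors (natural units), when fitted here.
    training_ranges
        Variable -> (min, max) observed in the training data; used for
        extrapolation diagnostics during transfer.
    log_likelihood, converged
        Fit diagnostics, when fitted here.
    notes
        Free-text provenance remarks.
    """

    intercept: float
    coefficients: dict[str, float]
    inclusion_order: dict[str, int] | None = None
    n1: int | None = None
    n0: int | None = None
    label: str = ""
    se: dict[str, float] | None = None
    intercept_se: float | None = None
    training_ranges: dict[str, tuple[float, float]] | None = None
    log_likelihood: float | None = None
    converged: bool | None = None
    notes: str = ""

    @property
    def variables(self) -> list[str]:
        return list(self.coefficients)

    @property
    def prevalence_odds(self) -> float:
        """Training odds n1/n0 used by the favourability correction."""
        if not (self.n1 and self.n0 and self.n1 > 0 and self.n0 > 0):
            raise InputError(
                f"model {self.label!r} has no training prevalence (n1, n0); "
                "supply one or use prevalence_source='target'"
            )
        return self.n1 / self.n0

    def rank_warnings(self) -> list[str]:
        """Report inclusion-order ranks that are not a permutation of 1..k.

        Published coefficient tables occasionally carry inconsistent ranks
        (duplicates or gaps); those are preserved verbatim and surfaced
        here rather than silently repaired.
        """
        if not self.inclusion_order:
            return []
        ranks = sorted(self.inclusion_order.values())
        expected = list(range(1, len(ranks) + 1))
        if ranks == expected:
            return []
        return [
            f"model {self.label!r}: inclusion ranks {ranks} are not a "
            f"permutation of {expected}"
        ]


@dataclass
class FavourabilitySurface:
    """Per-cell favourability F in [0, 1] with provenance."""

    values: np.ndarray
    model_label: str = ""
    prevalence_source: str = "training"
    cell_size: float = 8.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        valid = self.values[np.isfinite(self.values)]
        if ((valid < 0) | (valid > 1)).any():
            raise InputError("favourability values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Core transforms
# ---------------------------------------------------------------------------

def linear_predictor(coefs: CoefficientSet,
                     grid: EnvironmentalGrid) -> np.ndarray:
    """Evaluate ``y = intercept + sum_i beta_i x_i`` on every cell.

    Masked cells come back NaN. Raises :class:`InputError` naming the
    first model variable the grid does not provide.
    """
    missing = [v for v in coefs.variables if v not in grid.values]
    if missing:
        raise InputError(
            f"grid lacks model variable(s): {', '.join(missing)}"
        )
    y = np.full(grid.shape, float(coefs.intercept))
    for var, beta in coefs.coefficients.items():
        y = y + beta * grid.layer(var)
    y[~grid.valid_mask()] = np.nan
    return y


def favourability(p, n1: float, n0: float):
    """Prevalence-corrected favourability of a logistic probability.

    ``F = odds(P) / (n1/n0 + odds(P))``. Accepts scalars or arrays.
    F is strictly increasing in P, equals P when n1 == n0, and equals 0.5
    exactly at the training prevalence P = n1/(n1+n0). Endpoints map
    exactly: F(0) = 0, F(1) = 1. NaN propagates (masked cells).

    Raises :class:`InputError` for non-positive counts or P outside [0, 1].
    """
    if not (n1 > 0 and n0 > 0):
        raise InputError(f"n1 and n0 must be positive, got n1={n1}, n0={n0}")
    p_arr = np.asarray(p, dtype=float)
    finite = np.isfinite(p_arr)
    if ((p_arr[finite] < 0) | (p_arr[finite] > 1)).any():
        raise InputError("probabilities must lie in [0, 1]")
    ratio = n1 / n0
    clipped = np.clip(p_arr, EPS, 1.0 - EPS)
    odds = clipped / (1.0 - clipped)
    f = odds / (ratio + odds)
    # the transform's limits at the endpoints are exact
    f = np.where(p_arr == 0.0, 0.0, f)
    f = np.where(p_arr == 1.0, 1.0, f)
    f = np.where(finite, f, np.nan)
    return float(f) if np.isscalar(p) else f


def favourability_from_logit(y, n1: float, n0: float):
    """Favourability directly from the linear predictor: e^y/(n1/n0 + e^y).

    Numerically stable for large |y|; equivalent to
    ``favourability(expit(y), n1, n0)``.
    """
    if not (n1 > 0 and n0 > 0):
        raise InputError(f"n1 and n0 must be positive, got n1={n1}, n0={n0}")
    y = np.asarray(y, dtype=float)
    log_ratio = np.log(n1 / n0)
    # F = 1 / (1 + exp(log_ratio - y)), the logistic of (y - log n1/n0)
    from scipy.special import expit
    return expit(y - log_ratio)


def favourability_surface(coefs: CoefficientSet, grid: EnvironmentalGrid,
                          prevalence_source: str = "training",
                          target_det: DetectionGrid | None = None,
                          ) -> FavourabilitySurface:
    """Compose the linear predictor and favourability transform per cell.

    ``prevalence_source="training"`` anchors the 0.5 level at the model's
    own training prevalence (the coefficients and the correction travel
    together); ``"target"`` re-anchors on the prevalence of
    ``target_det``, useful when the target survey's prevalence is the more
    meaningful baseline.
    """
    if prevalence_source == "training":
        n1, n0 = coefs.n1, coefs.n0
        if not (n1 and n0):
            raise InputError(
                f"model {coefs.label!r} carries no training (n1, n0); "
                "required for prevalence_source='training'"
            )
    elif prevalence_source == "target":
        if target_det is None:
            raise InputError("prevalence_source='target' needs target_det")
        n1, n0 = target_det.n1, target_det.n0
        if not (n1 and n0):
            raise InputError("target detections have no presences or no absences")
    else:
        raise InputError(
            f"unknown prevalence_source {prevalence_source!r} "
            "(expected 'training' or 'target')"
        )
    y = linear_predictor(coefs, grid)
    f = favourability_from_logit(y, n1, n0)
    f = np.where(np.isnan(y), np.nan, f)
    return FavourabilitySurface(f, model_label=coefs.label,
                                prevalence_source=prevalence_source,
                                cell_size=grid.cell_size, origin=grid.origin,
                                mask=grid.mask)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _aligned_data(grid: EnvironmentalGrid, det: DetectionGrid,
                  variables: list[str]) -> tuple[np.ndarray, np.ndarray]:
    if grid.shape != det.shape:
        raise InputError(
            f"grid shape {grid.shape} != detection shape {det.shape}"
        )
    keep = grid.valid_mask().ravel() & det.observed_mask().ravel()
    if not keep.any():
        raise InputError("no cells with both covariates and an outcome")
    X = grid.design_matrix(variables)[keep]
    y = det.outcomes.ravel()[keep]
    return X, y


def fit_logistic(grid: EnvironmentalGrid, det: DetectionGrid,
                 variables: list[str], *, label: str = "fitted model",
                 tol: float = 1e-8, maxiter: int = 100) -> CoefficientSet:
    """Maximum-likelihood logistic regression of outcomes on grid covariates.

    Only cells that are valid in the grid and surveyed in ``det`` enter the
    likelihood. The returned :class:`CoefficientSet` records n1/n0 and the
    per-variable training ranges, so it is immediately usable for
    favourability surfaces and transfer diagnostics.

    With ``variables=[]`` the closed-form null model is returned:
    intercept = log(n1/n0).

    Complete separation is reported as a :class:`SeparationWarning` naming
    the diverging coefficients; a singular design raises
    :class:`InputError`.
    """
    X, y = _aligned_data(grid, det, list(variables))
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InputError(
            f"need at least one presence and one absence (n1={n1}, n0={n0})"
        )
    ranges = {v: (float(X[:, j].min()), float(X[:, j].max()))
              for j, v in enumerate(variables)}

    if not variables:
        intercept = float(np.log(n1 / n0))
        return CoefficientSet(
            intercept=intercept, coefficients={}, inclusion_order={},
            n1=n1, n0=n0, label=label,
            se={}, intercept_se=float(np.sqrt(1 / n1 + 1 / n0)),
            training_ranges={}, converged=True,
            log_likelihood=float(n1 * np.log(n1 / (n1 + n0))
                                 + n0 * np.log(n0 / (n1 + n0))),
        )

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        const = [v for j, v in enumerate(variables) if sd[j] == 0]
        raise InputError(
            f"constant-valued covariate(s) make the design singular: "
            f"{', '.join(const)}"
        )
    Z = (X - mean) / sd
    design = sm.add_constant(Z, has_constant="add")

    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(method="newton", tol=tol,
                                          maxiter=maxiter, disp=0)
        except np.linalg.LinAlgError as exc:
            raise InputError(f"singular design matrix: {exc}") from exc
        except Exception as exc:  # statsmodels PerfectSeparationError
            if "separation" in str(exc).lower() or type(exc).__name__.startswith(
                    "PerfectSeparation"):
                separated = True
                res = sm.Logit(y, design).fit(method="bfgs", maxiter=500,
                                              disp=0)
            else:
                raise
    for w in caught:
        if "separation" in str(w.message).lower():
            separated = True

    params = np.asarray(res.params)
    # direct check: the fitted linear predictor perfectly separating the
    # classes is the definition of complete separation (the MLE diverges)
    eta_hat = design @ params
    if eta_hat[y == 1].min() > eta_hat[y == 0].max() \
            and np.abs(params).max() > 20:
        separated = True
    cov_std = np.asarray(res.cov_params())
    k = len(variables)
    # back-transform standardized coefficients (and covariance) to raw units
    A = np.zeros((k + 1, k + 1))
    A[0, 0] = 1.0
    A[0, 1:] = -mean / sd
    A[1:, 1:] = np.diag(1.0 / sd)
    raw = A @ params
    cov_raw = A @ cov_std @ A.T
    se_raw = np.sqrt(np.maximum(np.diag(cov_raw), 0.0))

    coefs = {v: float(raw[j + 1]) for j, v in enumerate(variables)}
    ses = {v: float(se_raw[j + 1]) for j, v in enumerate(variables)}
    if separated:
        diverging = [v for v in variables
                     if ses[v] > 100 * max(abs(coefs[v]), 1.0) or
                     abs(coefs[v]) > 1e3]
        warnings.warn(
            "complete separation detected; diverging coefficients: "
            + (", ".join(f"{v}={coefs[v]:.3g}" for v in diverging)
               or "none identified"),
            SeparationWarning, stacklevel=2)

    return CoefficientSet(
        intercept=float(raw[0]), coefficients=coefs, inclusion_order=None,
        n1=n1, n0=n0, label=label, se=ses, intercept_se=float(se_raw[0]),
        training_ranges=ranges, log_likelihood=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True))
        if hasattr(res, "mle_retvals") else True,
    )


def forward_stepwise(grid: EnvironmentalGrid, det: DetectionGrid,
                     candidates: list[str], *, entry_alpha: float = 0.05,
                     criterion: str = "lrt", label: str = "stepwise model",
                     ) -> CoefficientSet:
    """Forward stepwise logistic selection, recording the order of inclusion.

    At each round the candidate with the smallest likelihood-ratio p-value
    against the current model is added while ``p < entry_alpha``
    (``criterion="lrt"``); with ``criterion="aic"`` the candidate with the
    largest AIC improvement is added while AIC improves. ``inclusion_order``
    on the returned model maps each selected variable to the round (1-based)
    at which it entered. ``entry_alpha=0`` admits nothing: the intercept-only
    model is returned.
    """
    if not candidates:
        raise InputError("candidates must be non-empty")
    if criterion not in ("lrt", "aic"):
        raise InputError(f"unknown criterion {criterion!r}")
    selected: list[str] = []
    order: dict[str, int] = {}
    current = fit_logistic(grid, det, selected, label=label)
    remaining = list(candidates)
    rank = 0
    while remaining:
        best_var, best_fit, best_score = None, None, None
        for var in remaining:
            try:
                trial = fit_logistic(grid, det, selected + [var], label=label)
            except InputError:
                continue  # e.g. constant covariate: cannot enter
            lr = 2.0 * (trial.log_likelihood - current.log_likelihood)
            if criterion == "lrt":
                score = stats.chi2.sf(max(lr, 0.0), df=1)
                better = best_score is None or score < best_score
            else:
                score = -(lr - 2.0)  # AIC change; negative = improvement
                better = best_score is None or score < best_score
            if better:
                best_var, best_fit, best_score = var, trial, score
        if best_var is None:
            break
        admit = (best_score < entry_alpha) if criterion == "lrt" \
            else (best_score < 0)
        if not admit:
            break
        rank += 1
        order[best_var] = rank
        selected.append(best_var)
        remaining.remove(best_var)
        current = best_fit
    current.inclusion_order = order
    return current


# ---------------------------------------------------------------------------
# CoefficientSet IO
# ---------------------------------------------------------------------------

def write_coefficients_csv(path: str | Path, coefs: CoefficientSet) -> None:
    """Write a model as CSV (variable, coefficient, inclusion_order) plus a
    ``<stem>.meta.json`` sidecar holding intercept, n1, n0, label and notes."""
    path = Path(path)
    rows = []
    for var in coefs.variables:
        rank = ""
        if coefs.inclusion_order and var in coefs.inclusion_order:
            rank = coefs.inclusion_order[var]
        rows.append({"variable": var,
                     "coefficient": repr(coefs.coefficients[var]),
                     "inclusion_order": rank})
    pd.DataFrame(rows, columns=["variable", "coefficient", "inclusion_order"]
                 ).to_csv(path, index=False)
    meta = {
        "label": coefs.label,
        "intercept": coefs.intercept,
        "n1": coefs.n1,
        "n0": coefs.n0,
        "notes": coefs.notes,
    }
    if coefs.training_ranges:
        meta["training_ranges"] = {v: list(r)
                                   for v, r in coefs.training_ranges.items()}
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def read_coefficients_csv(path: str | Path) -> CoefficientSet:
    """Read a model written by :func:`write_coefficients_csv`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    for col in ("variable", "coefficient"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    coefficients = {}
    order: dict[str, int] = {}
    for i, row in df.iterrows():
        var = str(row["variable"])
        try:
            coefficients[var] = float(row["coefficient"])
        except (TypeError, ValueError):
            raise InputError(
                f"{path}: row {i + 2}: bad coefficient {row['coefficient']!r}"
            ) from None
        rank = row.get("inclusion_order")
        if pd.notna(rank) and rank != "":
            order[var] = int(rank)
    meta_path = path.with_suffix(".meta.json")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    ranges = meta.get("training_ranges")
    return CoefficientSet(
        intercept=float(meta.get("intercept", 0.0)),
        coefficients=coefficients,
        inclusion_order=order or None,
        n1=meta.get("n1"), n0=meta.get("n0"),
        label=meta.get("label", path.stem),
        notes=meta.get("notes", ""),
        training_ranges={v: tuple(r) for v, r in ranges.items()}
        if ranges else None,
    )
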