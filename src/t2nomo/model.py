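"""Binary logistic regression, odds-ratio tables, nomogram and C-index.

The multivariate model is an ordinary maximum-likelihood logistic
regression on dichotomised histogram flags (fitted by iteratively
reweighted least squares via ``statsmodels``), reported as odds ratios
with Wald 95% confidence intervals. The nomogram is the standard
points-based rendering of such a model: predictor i spans
``100 * beta_i * range_i / max_j(beta_j * range_j)`` points (so exactly
one predictor reaches 100), and the total-points axis maps back to a
response probability through the model's own linear predictor - nomogram
scoring is therefore algebraically identical to evaluating the logistic
model. Discrimination is summarised by the concordance index, which for a
binary endpoint equals the rank AUC with half credit for ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import CollinearityError, DegenerateLabelsError, SchemaError, StateError
from .stats import _check_binary, _rank_auc

__all__ = [
    "LogisticFit",
    "NomogramModel",
    "fit_logistic",
    "or_forest_table",
    "build_nomogram",
    "score_nomogram",
    "c_index",
]

_Z95 = 1.959963984540054


@dataclass
class LogisticFit:
    """A fitted binary logistic regression on named predictors."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    intercept: float
    intercept_se: float
    converged: bool
    n_iterations: int
    n_obs: int
    max_score_residual: float

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        """(n_predictors, 2) Wald interval on the odds-ratio scale."""
        return np.exp(np.column_stack([self.beta - _Z95 * self.se,
                                       self.beta + _Z95 * self.se]))

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.beta / self.se
        return 2 * sps.norm.sf(np.abs(z))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.beta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))


def fit_logistic(X: pd.DataFrame, y: Sequence[int]) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS / Newton).

    Standard errors come from the inverse observed information. Perfect
    separation is reported through ``converged=False`` rather than an
    exception; a singular design raises :class:`CollinearityError`.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{i}" for i in range(np.shape(X)[1])])
    yv = _check_binary(np.asarray(y))
    if len(X) != len(yv):
        raise ValueError("X and y must have the same length")
    Xv = X.to_numpy(dtype=float)
    if np.any(Xv.std(axis=0) == 0):
        const = [c for c, s in zip(X.columns, Xv.std(axis=0)) if s == 0]
        raise CollinearityError(f"constant predictor column(s) {const}")
    design = np.column_stack([np.ones(len(Xv)), Xv])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is singular")

    converged = True
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(yv, design).fit(disp=0, method="newton", maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
    except (np.linalg.LinAlgError, PerfectSeparationError):
        with np.errstate(all="ignore"):
            res = sm.Logit(yv, design).fit(disp=0, method="bfgs",
                                           maxiter=200, gtol=1e-10)
        converged = False

    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        converged = False
    p_hat = 1.0 / (1.0 + np.exp(-design @ params))
    score = design.T @ (yv - p_hat)
    max_resid = float(np.max(np.abs(score)))
    if max_resid > 1e-8:
        converged = False
    return LogisticFit(
        names=list(X.columns), beta=params[1:], se=bse[1:],
        intercept=float(params[0]), intercept_se=float(bse[0]),
        converged=converged,
        n_iterations=int(res.mle_retvals.get("iterations", -1)),
        n_obs=len(yv), max_score_residual=max_resid)


def or_forest_table(fit: LogisticFit) -> pd.DataFrame:
    """Forest-plot table: one row per predictor with OR, Wald CI and p."""
    if fit is None or not isinstance(fit, LogisticFit):
        raise StateError("or_forest_table needs a fitted LogisticFit")
    ci = fit.ci95
    return pd.DataFrame({
        "predictor": fit.names,
        "beta": fit.beta,
        "se": fit.se,
        "or": fit.or_,
        "ci_lower": ci[:, 0],
        "ci_upper": ci[:, 1],
        "p_value": fit.p_values,
    })


@dataclass
class NomogramModel:
    """Points rendering of a logistic fit.

    ``points_per_unit[name]`` is the points awarded per unit of the
    predictor (binary predictors: the points of level 1). ``scale`` maps
    total points back to the linear predictor:
    lp = intercept + scale * total_points.
    """

    fit: LogisticFit
    points_per_unit: dict[str, float]
    scale: float
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "predictors": self.fit.names,
            "beta": list(map(float, self.fit.beta)),
            "se": list(map(float, self.fit.se)),
            "intercept": self.fit.intercept,
            "intercept_se": self.fit.intercept_se,
            "points_per_unit": self.points_per_unit,
            "scale": self.scale,
            "warnings": self.warnings,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NomogramModel":
        d = json.loads(text)
        fit = LogisticFit(
            names=list(d["predictors"]),
            beta=np.asarray(d["beta"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            intercept=float(d["intercept"]),
            intercept_se=float(d["intercept_se"]),
            converged=True, n_iterations=-1, n_obs=-1,
            max_score_residual=np.nan)
        return cls(fit=fit,
                   points_per_unit={k: float(v)
                                    for k, v in d["points_per_unit"].items()},
                   scale=float(d["scale"]),
                   warnings=list(d.get("warnings", [])))


def build_nomogram(fit: LogisticFit,
                   ranges: Mapping[str, float] | None = None) -> NomogramModel:
    """Standard 0-100 points construction over a converged fit.

    Predictor i's full-scale points are
    ``100 * beta_i * range_i / max_j(beta_j * range_j)``; binary
    predictors have range 1. A predictor whose ``beta * range`` is not
    positive contributes negative (or zero) points; this is recorded as a
    sign warning in the model metadata rather than silently dropped, so
    scoring stays identical to the logistic model.
    """
    if not fit.converged:
        raise StateError("cannot build a nomogram from a non-converged fit")
    r = np.array([1.0 if ranges is None else float(ranges[n])
                  for n in fit.names])
    contrib = fit.beta * r
    top = contrib.max()
    if top <= 0:
        raise StateError("no predictor with positive effect; nomogram undefined")
    warnings = [f"predictor {n!r} has non-positive beta*range "
                f"({c:.4g}); its points are non-positive"
                for n, c in zip(fit.names, contrib) if c <= 0]
    points_per_unit = {n: float(100.0 * b / top * 1.0)
                       for n, b in zip(fit.names, fit.beta)}
    return NomogramModel(fit=fit, points_per_unit=points_per_unit,
                         scale=float(top / 100.0), warnings=warnings)


def score_nomogram(model: NomogramModel,
                   values: Mapping[str, float]) -> tuple[float, float]:
    """Total points and response probability for one subject.

    The probability is computed through the total-points -> linear
    predictor map and agrees with direct logistic evaluation to numerical
    round-off.
    """
    unknown = set(values) - set(model.fit.names)
    if unknown:
        raise SchemaError(f"unknown predictor name(s) {sorted(unknown)}")
    missing = set(model.fit.names) - set(values)
    if missing:
        raise SchemaError(f"missing predictor value(s) {sorted(missing)}")
    total = float(sum(model.points_per_unit[n] * float(values[n])
                      for n in model.fit.names))
    lp = model.fit.intercept + model.scale * total
    prob = float(1.0 / (1.0 + np.exp(-lp)))
    return total, prob


def c_index(probabilities: Sequence[float], outcomes: Sequence[int]) -> float:
    """Concordance index; for a binary endpoint this is the rank AUC
    (ties get half credit)."""
    p = np.asarray(probabilities, dtype=float)
    y = _check_binary(outcomes)
    return _rank_auc(p, y)
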