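"""Internal and external model validation statistics.

Internal validation is leave-one-out cross-validation: Q² = 1 - PRESS / SS_y
with PRESS the sum of squared out-of-fold prediction errors.  Alongside Q²
the usual regression diagnostics are reported: R², their Wherry-adjusted
forms, the standard error of estimate, Fisher's F, per-compound residuals
(calculated minus experimental), the residual standard deviation SD_res, and
the 2 x SD_res outlier rule.  Cross-correlation matrices over descriptor
columns, potencies, or model residuals support redundancy analysis between
competing models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationReport",
    "CorrelationMatrix",
    "loo_q2",
    "adjusted",
    "residual_sd",
    "find_outliers",
    "cross_correlation",
    "f_statistic",
    "validate_model",
]

Fitter = Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]]


def _ols_fitter(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(beta[0]), beta[1:]


def loo_q2(X, y, fitter: Fitter | None = None) -> tuple[float, float]:
    """Leave-one-out Q² and PRESS.

    For each sample the model is refitted on the remaining n-1 and predicts
    the held-out activity; ``fitter`` maps (X, y) to (intercept,
    coefficients) and defaults to ordinary least squares.  Fold failures
    propagate annotated with the fold index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOO cross-validation needs at least 3 samples")
    fitter = fitter or _ols_fitter

    press = 0.0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            intercept, coef = fitter(X[mask], y[mask])
        except Exception as err:
            raise RuntimeError(f"refit failed on LOO fold {i}") from err
        mask[i] = True
        press += float((X[i] @ coef + intercept - y[i]) ** 2)
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss == 0:
        raise ValueError("activity vector has zero variance")
    return 1.0 - press / ss, press


def adjusted(stat: float, n: int, p: int) -> float:
    """Wherry adjustment: 1 - (1 - stat) (n - 1)/(n - p - 1), for R² or Q²."""
    if n - p - 1 <= 0:
        raise ValueError(f"adjustment undefined for n={n}, p={p}")
    return 1.0 - (1.0 - stat) * (n - 1) / (n - p - 1)


def residual_sd(residuals) -> float:
    """Sample standard deviation (n-1 denominator) of the fit residuals."""
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 residuals")
    return float(np.std(r, ddof=1))


def find_outliers(residuals, sd_res: float, ids: Sequence | None = None) -> set:
    """Compounds whose |residual| exceeds twice the residual SD."""
    if sd_res < 0:
        raise ValueError("sd_res must be non-negative")
    r = np.asarray(residuals, dtype=float)
    ids = list(ids) if ids is not None else list(range(len(r)))
    return {i for i, v in zip(ids, r) if abs(v) > 2.0 * sd_res}


def f_statistic(r2: float, n: int, p: int) -> float:
    """Fisher's F for a p-descriptor model: (R²/p) / ((1 - R²)/(n - p - 1))."""
    if n - p - 1 <= 0 or p < 1:
        raise ValueError(f"F undefined for n={n}, p={p}")
    if r2 >= 1:
        raise ValueError("F undefined for a perfect fit (R² = 1)")
    return (r2 / p) / ((1.0 - r2) / (n - p - 1))


@dataclass
class CorrelationMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        self.matrix = m
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")

    def to_frame(self) -> pd.DataFrame:
        labels = [str(l) for l in self.labels]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)

    def __getitem__(self, pair):
        a, b = pair
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def cross_correlation(columns: dict) -> CorrelationMatrix:
    """Pairwise Pearson correlations of named equal-length vectors.

    ``columns`` maps labels (descriptor keys, "potency", model names...) to
    vectors; a zero-variance column is reported by name in the error.
    """
    labels = list(columns)
    arrs = [np.asarray(columns[k], dtype=float) for k in labels]
    n = {a.size for a in arrs}
    if len(n) != 1:
        raise ValueError("columns must all have the same length")
    for lab, a in zip(labels, arrs):
        if np.var(a) == 0:
            raise ValueError(f"column {lab!r} has zero variance")
    mat = np.corrcoef(np.vstack(arrs))
    mat = np.atleast_2d(mat)
    return CorrelationMatrix(labels, mat)


@dataclass
class ValidationReport:
    r2: float
    r2_adj: float
    q2: float
    q2_adj: float
    se: float
    f_stat: float
    press: float
    residuals: dict
    sd_res: float
    outlier_ids: set
    n: int
    p: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "q2": self.q2,
            "q2_adj": self.q2_adj,
            "se": self.se,
            "f_stat": self.f_stat,
            "press": self.press,
            "sd_res": self.sd_res,
            "outlier_ids": sorted(self.outlier_ids),
            "n": self.n,
            "p": self.p,
            "residuals": {str(k): v for k, v in self.residuals.items()},
        }


def validate_model(
    X,
    y,
    predictions: np.ndarray | None = None,
    ids: Sequence | None = None,
    fitter: Fitter | None = None,
) -> ValidationReport:
    """Full internal-validation report for one descriptor subset.

    If ``predictions`` is omitted the model is fitted on (X, y) by ``fitter``
    (default OLS) to obtain calculated potencies; LOO statistics always refit
    fold by fold.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    ids = list(ids) if ids is not None else list(range(n))

    if predictions is None:
        intercept, coef = (fitter or _ols_fitter)(X, y)
        predictions = X @ coef + intercept
    resid = predictions - y
    lse = float(np.sum(resid**2))
    ss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - lse / ss
    q2, press = loo_q2(X, y, fitter)
    sd = residual_sd(resid)
    return ValidationReport(
        r2=r2,
        r2_adj=adjusted(r2, n, p),
        q2=q2,
        q2_adj=adjusted(q2, n, p),
        se=float(np.sqrt(lse / (n - p - 1))) if n - p - 1 > 0 else float("nan"),
        f_stat=f_statistic(r2, n, p) if r2 < 1 and n - p - 1 > 0 else float("inf"),
        press=press,
        residuals={i: float(r) for i, r in zip(ids, resid)},
        sd_res=sd,
        outlier_ids=find_outliers(resid, sd, ids),
        n=n,
        p=p,
    )
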