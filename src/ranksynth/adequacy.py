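"""Model-adequacy statistics for predicted-vs-observed comparisons.

Implements the classic agreement toolkit for evaluating prediction models in
animal nutrition: mean bias (MB = mean observed - mean predicted), mean square
error of prediction (MSEP, n denominator) with its exact three-component
decomposition into mean bias, slope bias and random error, Lin's concordance
correlation coefficient (CCC) with its accuracy factor C_b = CCC / r, adjusted
r-squared, and an AIC on the error scale.

Decomposition (population moments; s are n-denominator SDs, r the Pearson
correlation of observed and predicted):

    MSEP = MB^2 + (s_pred - r * s_obs)^2 + s_obs^2 * (1 - r^2)

which holds as an algebraic identity.  For in-sample OLS predictions the
mean-bias and slope-bias components are identically zero (fitted values have
mean ybar and SD r * s_y), so 100% of the MSEP is random error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AdequacyReport", "adequacy", "ols_fit", "OLSFit", "report_table"]


@dataclass(frozen=True)
class AdequacyReport:
    n: int
    p: int
    mean_pred: float
    mean_obs: float
    sd_pred: float          # n-1 denominator, for reporting
    sd_obs: float
    mb: float
    msep: float
    rmsep: float
    mse: float              # MSEP * n / (n - p)
    pct_mean_bias: float
    pct_slope_bias: float
    pct_random: float
    r: float
    r2_adj: float
    ccc: float
    cb: float
    aic: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def adequacy(observed, predicted, p: int) -> AdequacyReport:
    """All adequacy statistics for one observed/predicted pair.

    ``p`` is the model's parameter count (slopes + intercept for a linear
    model; by convention the number of predictors for a forest, which has no
    finite parameter count).  Perfect agreement (MSEP = 0) is reported as
    CCC = C_b = 1 with the percentage decomposition (0, 0, 100).
    """
    o = np.asarray(observed, dtype=float)
    pr = np.asarray(predicted, dtype=float)
    if o.shape != pr.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D vectors of equal length")
    n = len(o)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not (0 < p < n):
        raise ValueError(f"parameter count p={p} must satisfy 0 < p < n={n}")

    mb = float(o.mean() - pr.mean())
    msep = float(np.mean((o - pr) ** 2))
    so, sp = float(o.std()), float(pr.std())  # population (n) SDs

    if msep == 0.0:
        r = 1.0
        ccc = cb = 1.0
        pm, ps, prand = 0.0, 0.0, 100.0
        r2 = 1.0
    else:
        if so == 0 or sp == 0:
            raise ValueError("zero variance in observed or predicted; "
                             "correlation undefined")
        r = float(np.corrcoef(o, pr)[0, 1])
        comp_mean = mb ** 2
        comp_slope = (sp - r * so) ** 2
        comp_random = so ** 2 * (1 - r ** 2)
        pm = 100.0 * comp_mean / msep
        ps = 100.0 * comp_slope / msep
        prand = 100.0 * comp_random / msep
        ccc = 2 * r * so * sp / (so ** 2 + sp ** 2 + mb ** 2)
        cb = ccc / r
        r2 = r ** 2

    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    aic = n * math.log(msep) + 2 * (p + 1) if msep > 0 else -math.inf
    return AdequacyReport(
        n=n, p=p,
        mean_pred=float(pr.mean()), mean_obs=float(o.mean()),
        sd_pred=float(pr.std(ddof=1)), sd_obs=float(o.std(ddof=1)),
        mb=mb, msep=msep, rmsep=math.sqrt(msep), mse=msep * n / (n - p),
        pct_mean_bias=pm, pct_slope_bias=ps, pct_random=prand,
        r=r, r2_adj=r2_adj, ccc=ccc, cb=cb, aic=aic,
    )


@dataclass(frozen=True)
class OLSFit:
    """Least-squares fit with intercept; ``coefficients`` is indexed by
    'intercept' followed by the predictor names."""

    coefficients: pd.Series
    fitted: np.ndarray
    p: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cols = [c for c in self.coefficients.index if c != "intercept"]
        return (self.coefficients["intercept"]
                + X[cols].to_numpy(dtype=float) @ self.coefficients[cols].to_numpy())


def ols_fit(y, X: pd.DataFrame) -> OLSFit:
    """Ordinary least squares via QR, intercept included.

    Rank deficiency raises an error naming the collinear columns.
    """
    yv = np.asarray(y, dtype=float)
    names = ["intercept"] + list(X.columns)
    design = np.column_stack([np.ones(len(yv)), X.to_numpy(dtype=float)])
    n, p = design.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    q, r_mat = np.linalg.qr(design)
    diag = np.abs(np.diag(r_mat))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    if np.any(diag < tol):
        bad = [names[i] for i in np.where(diag < tol)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta = np.linalg.solve(r_mat, q.T @ yv)
    fitted = design @ beta
    return OLSFit(pd.Series(beta, index=names), fitted, p)


_TABLE_ROWS = [
    ("N", "n"), ("Mean predicted", "mean_pred"), ("Mean observed", "mean_obs"),
    ("MB", "mb"), ("SD predicted", "sd_pred"), ("SD observed", "sd_obs"),
    ("RMSE", "rmsep"), ("r2", "r2_adj"), ("CCC", "ccc"), ("Cb", "cb"),
    ("MSE", "mse"), ("MB,%", "pct_mean_bias"), ("Slope,%", "pct_slope_bias"),
    ("Random,%", "pct_random"), ("AIC", "aic"),
]


def report_table(reports: dict[str, AdequacyReport]) -> pd.DataFrame:
    """Render named reports as a statistics-by-scenario table."""
    return pd.DataFrame({name: [getattr(rep, attr) for _, attr in _TABLE_ROWS]
                         for name, rep in reports.items()},
                        index=[label for label, _ in _TABLE_ROWS])
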