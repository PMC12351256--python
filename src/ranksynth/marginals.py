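"""Parametric marginal distributions: fitting, AIC-based family selection, sampling.

Each column of a tabular database is modelled by one univariate family from a
curated catalog of twelve continuous distributions covering the shapes that
arise in nutrition databases (right-skewed intakes and emissions, bounded
percentage-scale diet components, heavy-tailed residual traits).  Fitting is
maximum likelihood; families are compared by AIC = 2k - 2*logL.  The catalog is
a registry, so additional families can be plugged in without touching callers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FittedMarginal",
    "Family",
    "FAMILY_CATALOG",
    "fit_marginal",
    "best_fit",
    "sample_marginal",
    "fit_marginals_table",
    "manifest_to_json",
    "manifest_from_json",
    "SupportError",
    "FitError",
]


class SupportError(ValueError):
    """Data lie outside the support of the requested family."""


class FitError(RuntimeError):
    """Maximum-likelihood optimisation failed to produce finite estimates."""


@dataclass(frozen=True)
class Family:
    """One catalog entry: canonical parameterisation plus fit/freeze recipes.

    ``fit`` maps a data vector to the canonical parameter tuple; ``freeze``
    maps that tuple to a frozen scipy distribution.  ``n_free`` is the number
    of estimated parameters entering AIC (declared envelope bounds, as used by
    the beta family on percentage data, do not count as estimated).
    """

    name: str
    param_names: tuple[str, ...]
    n_free: int
    fit: Callable[[np.ndarray], tuple[float, ...]]
    freeze: Callable[[tuple[float, ...]], stats.rv_continuous]
    feasible: Callable[[np.ndarray], str | None]
    support: Callable[[tuple[float, ...]], tuple[float, float]]


@dataclass(frozen=True)
class FittedMarginal:
    """A fitted parametric marginal for one named column."""

    column_name: str
    family: str
    params: tuple[float, ...]
    support: tuple[float, float]
    log_likelihood: float
    aic: float
    n_fit: int

    def frozen(self):
        """Frozen scipy distribution in the family's canonical parameterisation."""
        return FAMILY_CATALOG[self.family].freeze(self.params)

    # Beta on a declared envelope stores (a, b, lo, hi); its frozen dist is
    # already loc/scale-shifted, so cdf/ppf/pdf below work uniformly.
    def cdf(self, x):
        return self.frozen().cdf(x)

    def ppf(self, q):
        return self.frozen().ppf(q)

    def pdf(self, x):
        return self.frozen().pdf(x)

    def mean(self) -> float:
        return float(self.frozen().mean())

    def var(self) -> float:
        return float(self.frozen().var())

    def to_dict(self) -> dict:
        return {
            "column": self.column_name,
            "family": self.family,
            "params": list(self.params),
            "support": list(self.support),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_fit": self.n_fit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedMarginal":
        return cls(
            column_name=d["column"],
            family=d["family"],
            params=tuple(d["params"]),
            support=tuple(d["support"]),
            log_likelihood=d["log_likelihood"],
            aic=d["aic"],
            n_fit=d["n_fit"],
        )


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------


def _positive(x: np.ndarray) -> str | None:
    if np.min(x) <= 0:
        return "requires strictly positive values"
    return None


def _any(x: np.ndarray) -> str | None:
    return None


def _beta_feasible(x: np.ndarray) -> str | None:
    if not (0.0 < np.min(x) and np.max(x) < 1.0):
        return ("requires values in (0, 1); declare an envelope, e.g. "
                "envelope=(0, 100) for percentage-scale data")
    return None


def _fit_normal(x):
    # Gaussian MLE in closed form: sample mean, SD with 1/n denominator.
    return (float(np.mean(x)), float(np.std(x)))


def _fit_lognormal(x):
    lx = np.log(x)
    return (float(np.mean(lx)), float(np.std(lx)))


def _fit_exponential(x):
    return (float(np.mean(x)),)


def _scipy_fit(dist, x, **fixed):
    res = dist.fit(x, **fixed)
    if not np.all(np.isfinite(res)):
        raise FitError(f"{dist.name} fit produced non-finite parameters {res}")
    return res


def _fit_gamma(x):
    a, _, scale = _scipy_fit(stats.gamma, x, floc=0)
    return (float(a), float(scale))


def _fit_chisquare(x):
    df, _, _ = _scipy_fit(stats.chi2, x, floc=0, fscale=1)
    return (float(df),)


def _fit_beta(x):
    # data validated to lie in (0, 1); declared envelopes are handled by
    # fit_marginal rescaling before dispatch
    a, b, _, _ = _scipy_fit(stats.beta, x, floc=0, fscale=1)
    return (float(a), float(b), 0.0, 1.0)


def _fit_weibull(x):
    c, _, scale = _scipy_fit(stats.weibull_min, x, floc=0)
    return (float(c), float(scale))


def _fit_loglogistic(x):
    c, _, scale = _scipy_fit(stats.fisk, x, floc=0)
    return (float(c), float(scale))


def _fit_triangular(x):
    c, loc, scale = _scipy_fit(stats.triang, x)
    return (float(loc), float(loc + c * scale), float(loc + scale))


def _fit_skewnormal(x):
    a, loc, scale = _scipy_fit(stats.skewnorm, x)
    return (float(a), float(loc), float(scale))


def _fit_t(x):
    df, loc, scale = _scipy_fit(stats.t, x)
    return (float(df), float(loc), float(scale))


def _fit_logistic(x):
    loc, scale = _scipy_fit(stats.logistic, x)
    return (float(loc), float(scale))


_INF = math.inf

#: Catalog order doubles as the tie-break order in :func:`best_fit`.
FAMILY_CATALOG: dict[str, Family] = {}


def register_family(fam: Family) -> None:
    FAMILY_CATALOG[fam.name] = fam


for fam in [
    Family("normal", ("mu", "sigma"), 2, _fit_normal,
           lambda p: stats.norm(p[0], p[1]), _any, lambda p: (-_INF, _INF)),
    Family("lognormal", ("mu_log", "sigma_log"), 2, _fit_lognormal,
           lambda p: stats.lognorm(s=p[1], scale=math.exp(p[0])), _positive,
           lambda p: (0.0, _INF)),
    Family("gamma", ("shape", "scale"), 2, _fit_gamma,
           lambda p: stats.gamma(p[0], scale=p[1]), _positive,
           lambda p: (0.0, _INF)),
    Family("exponential", ("scale",), 1, _fit_exponential,
           lambda p: stats.expon(scale=p[0]), _positive, lambda p: (0.0, _INF)),
    Family("chisquare", ("df",), 1, _fit_chisquare,
           lambda p: stats.chi2(p[0]), _positive, lambda p: (0.0, _INF)),
    Family("beta", ("a", "b", "lo", "hi"), 2, _fit_beta,
           lambda p: stats.beta(p[0], p[1], loc=p[2], scale=p[3] - p[2]),
           _beta_feasible, lambda p: (p[2], p[3])),
    Family("weibull", ("shape", "scale"), 2, _fit_weibull,
           lambda p: stats.weibull_min(p[0], scale=p[1]), _positive,
           lambda p: (0.0, _INF)),
    Family("loglogistic", ("shape", "scale"), 2, _fit_loglogistic,
           lambda p: stats.fisk(p[0], scale=p[1]), _positive,
           lambda p: (0.0, _INF)),
    Family("triangular", ("lo", "mode", "hi"), 3, _fit_triangular,
           lambda p: stats.triang((p[1] - p[0]) / (p[2] - p[0]), loc=p[0],
                                  scale=p[2] - p[0]), _any,
           lambda p: (p[0], p[2])),
    Family("skewnormal", ("a", "loc", "scale"), 3, _fit_skewnormal,
           lambda p: stats.skewnorm(p[0], loc=p[1], scale=p[2]), _any,
           lambda p: (-_INF, _INF)),
    Family("t", ("df", "loc", "scale"), 3, _fit_t,
           lambda p: stats.t(p[0], loc=p[1], scale=p[2]), _any,
           lambda p: (-_INF, _INF)),
    Family("logistic", ("loc", "scale"), 2, _fit_logistic,
           lambda p: stats.logistic(loc=p[0], scale=p[1]), _any,
           lambda p: (-_INF, _INF)),
]:
    register_family(fam)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _validate_values(values, column: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"column {column!r}: expected a 1-D vector")
    if len(x) < 10:
        raise ValueError(f"column {column!r}: need at least 10 values, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"column {column!r}: contains non-finite values")
    return x


def fit_marginal(values: Sequence[float], family: str, column: str = "value",
                 envelope: tuple[float, float] | None = None) -> FittedMarginal:
    """Fit one family to one column by maximum likelihood.

    ``envelope`` is a declared (lo, hi) support used by the beta family to
    rescale data outside (0, 1) -- e.g. (0, 100) for percentage-scale diet
    components; the bounds are declared, not estimated, and are stored in the
    parameter vector.  Raises :class:`SupportError` when the data violate the
    family's support (the message names both the offending column and the
    family), and :class:`FitError` when the optimiser fails.
    """
    if family not in FAMILY_CATALOG:
        raise KeyError(f"unknown family {family!r}; catalog: {list(FAMILY_CATALOG)}")
    x = _validate_values(values, column)
    fam = FAMILY_CATALOG[family]
    if family == "beta" and envelope is not None:
        lo, hi = float(envelope[0]), float(envelope[1])
        if not (lo < np.min(x) and np.max(x) < hi):
            raise SupportError(
                f"column {column!r}, family 'beta': values outside the declared "
                f"envelope ({lo:g}, {hi:g})")
        scaled = fit_marginal((x - lo) / (hi - lo), "beta", column=column)
        a, b = scaled.params[0], scaled.params[1]
        # log-likelihood on the original scale: subtract n*log(hi - lo)
        ll = scaled.log_likelihood - len(x) * math.log(hi - lo)
        return FittedMarginal(column, "beta", (a, b, lo, hi), (lo, hi),
                              ll, 2 * fam.n_free - 2 * ll, len(x))
    reason = fam.feasible(x)
    if reason is not None:
        raise SupportError(f"column {column!r}, family {family!r}: {reason}")
    if family == "normal" and np.std(x) == 0:
        raise FitError(f"column {column!r}: zero variance, degenerate normal fit rejected")
    try:
        params = fam.fit(x)
    except SupportError:
        raise
    except FitError:
        raise
    except Exception as e:  # optimizer diagnostics travel with the error
        raise FitError(f"column {column!r}, family {family!r}: fit failed ({e})") from e
    dist = fam.freeze(params)
    ll = float(np.sum(dist.logpdf(x)))
    if not np.isfinite(ll):
        raise FitError(
            f"column {column!r}, family {family!r}: non-finite log-likelihood "
            f"at params {params}")
    aic = 2 * fam.n_free - 2 * ll
    return FittedMarginal(column, family, tuple(params), fam.support(params),
                          ll, aic, len(x))


def best_fit(values: Sequence[float], candidates: Sequence[str] | None = None,
             column: str = "value",
             envelope: tuple[float, float] | None = None) -> FittedMarginal:
    """Fit every feasible candidate family and return the minimal-AIC fit.

    Families whose support excludes the data are skipped silently; ties are
    broken by fewer parameters, then by catalog order.  If every candidate is
    infeasible or fails, the error lists the per-family reasons.
    """
    if candidates is None:
        candidates = list(FAMILY_CATALOG)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    order = {name: i for i, name in enumerate(FAMILY_CATALOG)}
    fits: list[FittedMarginal] = []
    skipped: dict[str, str] = {}
    for name in candidates:
        try:
            fits.append(fit_marginal(values, name, column=column,
                                     envelope=envelope))
        except (SupportError, FitError) as e:
            skipped[name] = str(e)
    if not fits:
        detail = "; ".join(f"{k}: {v}" for k, v in skipped.items())
        raise SupportError(f"column {column!r}: no feasible candidate family ({detail})")
    return min(fits, key=lambda m: (m.aic, FAMILY_CATALOG[m.family].n_free,
                                    order[m.family]))


def sample_marginal(m: FittedMarginal, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. values from a fitted marginal, reproducibly."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return np.asarray(m.frozen().rvs(size=n, random_state=rng), dtype=float)


def fit_marginals_table(data: pd.DataFrame, mode: str = "best_fit",
                        candidates: Sequence[str] | None = None,
                        beta_envelopes: dict[str, tuple[float, float]] | None = None,
                        ) -> dict[str, FittedMarginal]:
    """Fit a marginal per column: all-normal or AIC-selected best fit.

    ``beta_envelopes`` declares per-column (lo, hi) supports under which the
    beta family competes for columns outside (0, 1) -- typically (0, 100) for
    percentage-scale diet components.  Columns without a declared envelope
    simply skip beta unless their data already lie in the unit interval.
    """
    if mode not in ("normal_only", "best_fit"):
        raise ValueError(f"mode must be 'normal_only' or 'best_fit', got {mode!r}")
    beta_envelopes = beta_envelopes or {}
    out = {}
    for col in data.columns:
        if mode == "normal_only":
            out[col] = fit_marginal(data[col].to_numpy(), "normal", column=col)
        else:
            out[col] = best_fit(data[col].to_numpy(), candidates, column=col,
                                envelope=beta_envelopes.get(col))
    return out


def manifest_to_json(marginals: dict[str, FittedMarginal]) -> str:
    """Serialise a fitted-marginal manifest (column -> family/params/aic)."""
    return json.dumps({c: m.to_dict() for c, m in marginals.items()}, indent=2)


def manifest_from_json(text: str) -> dict[str, FittedMarginal]:
    raw = json.loads(text)
    return {c: FittedMarginal.from_dict(d) for c, d in raw.items()}
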