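"""Random-forest and linear predictors with importance and 2x2 cross-testing.

The forest is a scikit-learn ``RandomForestRegressor`` (variance-reduction
splitting, per-tree bootstrap) behind this module's surface.  Two importance
indices are computed from the fitted trees:

* PAS (predictive accuracy score): the percentage increase in a tree's
  out-of-bag MSE when one predictor's values are permuted, averaged over
  trees.  Reported unscaled (raw percent, not divided by its SE).
* SER (square error reduction): the residual-sum-of-squares decrease
  attributable to splits on a variable, summed over a tree's nodes and
  averaged across trees; units are the squared response units.

Cross-testing fits RF and LM on each of two databases (e.g. normal-marginals
vs best-fit-marginals synthetic data) and evaluates every fitted model on both
databases through the adequacy statistics, yielding the four-cell grid per
model family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .adequacy import AdequacyReport, adequacy, ols_fit

def _bootstrap_indices(random_state, n_samples: int) -> np.ndarray:
    """Rows sampled into a tree's bootstrap: the literal draw scikit-learn
    performs for each estimator (uniform with replacement, n of n, seeded by
    the estimator's ``random_state``)."""
    return np.random.RandomState(random_state).randint(0, n_samples, n_samples)

__all__ = ["RFModel", "ImportanceReport", "CrossTestGrid", "fit_rf",
           "importance", "cross_test"]


@dataclass
class RFModel:
    """Fitted regression forest plus the training frame needed for OOB work."""

    forest: RandomForestRegressor
    predictors: tuple[str, ...]
    response: str
    X: np.ndarray
    y: np.ndarray

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(data[list(self.predictors)].to_numpy(dtype=float))

    def oob_indices(self, tree_index: int) -> np.ndarray:
        n = len(self.y)
        tree = self.forest.estimators_[tree_index]
        sampled = _bootstrap_indices(tree.random_state, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        return np.where(mask)[0]

    def oob_predictions(self) -> np.ndarray:
        """Per-row mean prediction over the trees not trained on that row."""
        n = len(self.y)
        total = np.zeros(n)
        count = np.zeros(n)
        for t, tree in enumerate(self.forest.estimators_):
            oob = self.oob_indices(t)
            if len(oob) == 0:
                continue
            total[oob] += tree.predict(self.X[oob])
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    def oob_mse(self) -> float:
        pred = self.oob_predictions()
        ok = ~np.isnan(pred)
        return float(np.mean((self.y[ok] - pred[ok]) ** 2))


@dataclass(frozen=True)
class ImportanceReport:
    """Per-variable PAS (percent) and SER (squared response units)."""

    pas: pd.Series
    ser: pd.Series
    total_impurity_decrease: float  # bookkeeping check: equals ser.sum()

    def ranked(self) -> pd.DataFrame:
        """Variables sorted by descending SER (the usual plot layout)."""
        return (pd.DataFrame({"pas": self.pas, "ser": self.ser})
                .sort_values("ser", ascending=False))


@dataclass
class CrossTestGrid:
    """Adequacy reports keyed by (training db, evaluation db, model)."""

    response: str
    cells: dict[tuple[str, str, str], AdequacyReport]

    def cell(self, train: str, evaluate: str, model: str) -> AdequacyReport:
        return self.cells[(train, evaluate, model)]

    def to_table(self) -> pd.DataFrame:
        from .adequacy import report_table
        return report_table({f"{m} {t}->{e}": rep
                             for (t, e, m), rep in self.cells.items()})


def fit_rf(data: pd.DataFrame, response: str, n_trees: int = 150,
           m_try: int = 4, seed: int = 0, min_node: int = 5) -> RFModel:
    """Fit a regression forest (defaults: 150 trees, 4 candidate variables per
    split, minimum node size 5, bootstrap of n rows with replacement)."""
    if response not in data.columns:
        raise ValueError(f"response {response!r} not in data")
    predictors = tuple(c for c in data.columns if c != response)
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    if m_try > len(predictors):
        raise ValueError(f"m_try={m_try} exceeds predictor count {len(predictors)}")
    X = data[list(predictors)].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=m_try, min_samples_leaf=min_node,
        bootstrap=True, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return RFModel(forest, predictors, response, X, y)


def _tree_impurity_decrease(tree, n_features: int) -> np.ndarray:
    """Per-feature RSS decrease summed over a tree's internal nodes.

    A node's impurity is its MSE, so weighted impurity (w * MSE) is the node
    RSS; the decrease at a split is parent RSS minus child RSS sums.
    """
    t = tree.tree_
    dec = np.zeros(n_features)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        rss_parent = t.weighted_n_node_samples[node] * t.impurity[node]
        rss_children = (t.weighted_n_node_samples[left] * t.impurity[left]
                        + t.weighted_n_node_samples[right] * t.impurity[right])
        dec[t.feature[node]] += rss_parent - rss_children
    return dec


def importance(model: RFModel, seed: int = 0) -> ImportanceReport:
    """PAS by OOB permutation and SER by split-wise RSS accounting."""
    rng = np.random.default_rng(seed)
    k = len(model.predictors)
    n_trees = len(model.forest.estimators_)

    pas_sum = np.zeros(k)
    pas_count = np.zeros(k)
    ser_sum = np.zeros(k)
    total_dec = 0.0
    for t, tree in enumerate(model.forest.estimators_):
        dec = _tree_impurity_decrease(tree, k)
        ser_sum += dec
        total_dec += dec.sum()
        oob = model.oob_indices(t)
        if len(oob) < 2:
            continue
        X_oob, y_oob = model.X[oob], model.y[oob]
        base = float(np.mean((y_oob - tree.predict(X_oob)) ** 2))
        if base == 0:
            continue
        for j in range(k):
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            mse_perm = float(np.mean((y_oob - tree.predict(Xp)) ** 2))
            pas_sum[j] += 100.0 * (mse_perm - base) / base
            pas_count[j] += 1

    pas = pas_sum / np.maximum(pas_count, 1)
    ser = ser_sum / n_trees
    names = list(model.predictors)
    return ImportanceReport(pd.Series(pas, index=names, name="pas"),
                            pd.Series(ser, index=names, name="ser"),
                            total_dec / n_trees)


def cross_test(db_normal: pd.DataFrame, db_nonnormal: pd.DataFrame,
               response: str, seed: int = 0, n_trees: int = 150,
               m_try: int = 4) -> CrossTestGrid:
    """Fit RF and LM on each database, evaluate each on both via adequacy.

    Parameter counts for adequacy: predictors + 1 for the linear model; the
    predictor count for the forest (a documented stand-in, since a forest has
    no finite parameter count).
    """
    if set(db_normal.columns) != set(db_nonnormal.columns):
        raise ValueError("the two databases must share an identical column set")
    dbs = {"normal": db_normal, "nonnormal": db_nonnormal}
    predictors = [c for c in db_normal.columns if c != response]
    p_lm = len(predictors) + 1
    p_rf = len(predictors)

    fitted = {}
    for name, db in dbs.items():
        fitted[("RF", name)] = fit_rf(db, response, n_trees=n_trees,
                                      m_try=min(m_try, len(predictors)), seed=seed)
        fitted[("LM", name)] = ols_fit(db[response], db[predictors])

    cells = {}
    for (model_kind, train), model in fitted.items():
        for ev, db in dbs.items():
            obs = db[response].to_numpy(dtype=float)
            if model_kind == "RF":
                pred = model.predict(db)
                cells[(train, ev, "RF")] = adequacy(obs, pred, p_rf)
            else:
                pred = model.predict(db[predictors])
                cells[(train, ev, "LM")] = adequacy(obs, pred, p_lm)
    return CrossTestGrid(response, cells)
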