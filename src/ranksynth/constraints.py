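"""Declarative cleaning of tabular data: bounds, pairwise order, sum caps,
and statistical outlier rules.

Rows are dropped, never edited.  Deterministic rules (bounds / order / sums)
live in :func:`apply_constraints`; statistical outlier rules (z-score, IQR)
live in :func:`flag_outliers` so they can be applied to a real database before
marginal fitting as well as, optionally, to synthetic tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConstraintSet", "apply_constraints", "flag_outliers"]


@dataclass(frozen=True)
class ConstraintSet:
    """Bounds are open intervals (lo, hi); order pairs require lesser < greater
    row-wise; sum caps require sum(columns) < cap; outlier rules are
    (column, method in {zscore, iqr}, threshold)."""

    bounds: tuple = ()
    order_pairs: tuple = ()
    sum_caps: tuple = ()
    outlier_rules: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "bounds", tuple((c, float(lo), float(hi))
                                                 for c, lo, hi in self.bounds))
        object.__setattr__(self, "order_pairs", tuple((a, b)
                                                      for a, b in self.order_pairs))
        object.__setattr__(self, "sum_caps", tuple((tuple(cols), float(cap))
                                                   for cols, cap in self.sum_caps))
        object.__setattr__(self, "outlier_rules",
                           tuple((c, m, float(t)) for c, m, t in self.outlier_rules))
        for cols, cap in self.sum_caps:
            if cap <= 0:
                raise ValueError(f"sum cap for {cols} must be strictly positive")
        for c, m, t in self.outlier_rules:
            if m not in ("zscore", "iqr"):
                raise ValueError(f"outlier method must be 'zscore' or 'iqr', got {m!r}")
            if t <= 0:
                raise ValueError(f"outlier threshold for {c!r} must be strictly positive")

    def referenced_columns(self) -> set[str]:
        cols = {c for c, _, _ in self.bounds}
        for a, b in self.order_pairs:
            cols |= {a, b}
        for cs, _ in self.sum_caps:
            cols |= set(cs)
        cols |= {c for c, _, _ in self.outlier_rules}
        return cols

    def to_json(self) -> str:
        return json.dumps({
            "bounds": [list(b) for b in self.bounds],
            "order_pairs": [list(p) for p in self.order_pairs],
            "sum_caps": [[list(cs), cap] for cs, cap in self.sum_caps],
            "outlier_rules": [list(r) for r in self.outlier_rules],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConstraintSet":
        d = json.loads(text)
        return cls(
            bounds=tuple(tuple(b) for b in d.get("bounds", ())),
            order_pairs=tuple(tuple(p) for p in d.get("order_pairs", ())),
            sum_caps=tuple((tuple(cs), cap) for cs, cap in d.get("sum_caps", ())),
            outlier_rules=tuple(tuple(r) for r in d.get("outlier_rules", ())),
        )


def _check_columns(data: pd.DataFrame, cs: ConstraintSet,
                   deterministic_only: bool = False) -> None:
    wanted = cs.referenced_columns() if not deterministic_only else (
        {c for c, _, _ in cs.bounds}
        | {c for pair in cs.order_pairs for c in pair}
        | {c for cols, _ in cs.sum_caps for c in cols})
    missing = wanted - set(data.columns)
    if missing:
        raise KeyError(f"constraint references unknown columns: {sorted(missing)}")


def apply_constraints(data: pd.DataFrame, cs: ConstraintSet
                      ) -> tuple[pd.DataFrame, dict]:
    """Keep rows satisfying every deterministic constraint.

    The removal log counts removals per rule; a row violating several rules is
    attributed to the first violated rule in declaration order (bounds, then
    order pairs, then sum caps) and counted once in the total.  The surviving
    set itself is order-independent.
    """
    if len(data) == 0:
        raise ValueError("data is empty")
    _check_columns(data, cs, deterministic_only=True)

    rules: list[tuple[str, np.ndarray]] = []  # (label, satisfied-mask)
    for col, lo, hi in cs.bounds:
        v = data[col].to_numpy(dtype=float)
        rules.append((f"bound:{col}", (v > lo) & (v < hi)))
    for lesser, greater in cs.order_pairs:
        rules.append((f"order:{lesser}<{greater}",
                      data[lesser].to_numpy(dtype=float)
                      < data[greater].to_numpy(dtype=float)))
    for cols, cap in cs.sum_caps:
        s = data[list(cols)].to_numpy(dtype=float).sum(axis=1)
        rules.append((f"sum:{'+'.join(cols)}<{cap:g}", s < cap))

    keep = np.ones(len(data), dtype=bool)
    attributed = np.zeros(len(data), dtype=bool)
    log = {}
    for label, ok in rules:
        viol = ~ok
        log[label] = int(np.sum(viol & ~attributed))
        attributed |= viol
        keep &= ok
    log["total"] = int(np.sum(~keep))
    return data.loc[keep].reset_index(drop=True), log


def flag_outliers(data: pd.DataFrame, cs: ConstraintSet) -> pd.Series:
    """Per-row keep mask under the statistical outlier rules.

    zscore drops rows with |x - mean| / SD > threshold; iqr drops rows outside
    [Q1 - t*IQR, Q3 + t*IQR] with type-7 (linear-interpolation) quartiles.
    An infinite threshold keeps everything.
    """
    if not cs.outlier_rules:
        raise ValueError("ConstraintSet has no outlier rules")
    _check_columns(data, cs)
    keep = np.ones(len(data), dtype=bool)
    for col, method, t in cs.outlier_rules:
        v = data[col].to_numpy(dtype=float)
        if method == "zscore":
            sd = v.std()
            if sd == 0:
                raise ValueError(f"column {col!r} has zero variance; "
                                 "z-score rule undefined")
            keep &= np.abs(v - v.mean()) / sd <= t
        else:  # iqr
            if math.isinf(t):
                continue
            q1, q3 = np.percentile(v, [25, 75])
            iqr = q3 - q1
            keep &= (v >= q1 - t * iqr) & (v <= q3 + t * iqr)
    return pd.Series(keep, index=data.index, name="keep")
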