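"""Orchestration of the four-step synthetic-database pipeline.

Step 1 fits marginals (done by the caller or via
:func:`ranksynth.marginals.fit_marginals_table`); step 2 samples each column
independently; step 3 imposes the target Spearman structure by the rank-based
method; step 4 cleans the table against a declarative constraint set.  The
default order runs correlation before cleaning, so the delivered table is
guaranteed to satisfy every deterministic constraint; the literal
clean-then-correlate order is retained as a mode for fidelity experiments, in
which case the manifest reports how many delivered rows violate constraints
(reordering columns after cleaning can re-create row-level violations).

Every run emits a manifest (seeds, removal counts, final n, realized Spearman
matrix, per-column moment comparison against the fitted marginals) so results
are reproducible from the manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constraints import ConstraintSet, apply_constraints
from .marginals import FittedMarginal, sample_marginal
from .rank_correlate import (CorrelationDeviation, SpearmanTarget,
                             impose_rank_correlation, spearman_matrix)

__all__ = ["SynthesisPlan", "synthesize", "realized_correlation_report"]


@dataclass(frozen=True)
class SynthesisPlan:
    n_records: int
    target: SpearmanTarget
    constraints: ConstraintSet = ConstraintSet()
    mode: str = "best_fit"                 # normal_only | best_fit (bookkeeping)
    order: str = "correlate_then_clean"    # or clean_then_correlate
    seed: int = 0

    def __post_init__(self):
        if self.order not in ("correlate_then_clean", "clean_then_correlate"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.mode not in ("normal_only", "best_fit"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_records < 10 * len(self.target.columns):
            raise ValueError(
                f"n_records={self.n_records} < 10 x {len(self.target.columns)} columns")


class TooFewSurvivorsError(RuntimeError):
    pass


def _column_seeds(master: int, columns) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(columns) + 1)
    return {c: int(ch.generate_state(1)[0] % (2 ** 31))
            for c, ch in zip(columns, children[:-1])}, int(
                children[-1].generate_state(1)[0] % (2 ** 31))


def synthesize(marginals: dict[str, FittedMarginal], plan: SynthesisPlan
               ) -> tuple[pd.DataFrame, dict]:
    """Generate, correlate, and clean one synthetic database.

    ``marginals`` must cover every target column.  Returns the table and its
    manifest.  Raises :class:`TooFewSurvivorsError` when fewer than 100 rows
    survive cleaning.
    """
    missing = set(plan.target.columns) - set(marginals)
    if missing:
        raise ValueError(f"marginals missing for target columns {sorted(missing)}")

    col_seeds, impose_seed = _column_seeds(plan.seed, plan.target.columns)
    raw = pd.DataFrame({c: sample_marginal(marginals[c], plan.n_records,
                                           col_seeds[c])
                        for c in plan.target.columns})

    has_rules = bool(plan.constraints.bounds or plan.constraints.order_pairs
                     or plan.constraints.sum_caps)
    if plan.order == "correlate_then_clean":
        correlated = impose_rank_correlation(raw, plan.target, seed=impose_seed)
        if has_rules:
            final, removal_log = apply_constraints(correlated, plan.constraints)
        else:
            final, removal_log = correlated, {"total": 0}
        violations_after = 0
    else:
        if has_rules:
            cleaned, removal_log = apply_constraints(raw, plan.constraints)
        else:
            cleaned, removal_log = raw, {"total": 0}
        final = impose_rank_correlation(cleaned, plan.target, seed=impose_seed)
        if has_rules:
            recheck, _ = apply_constraints(final, plan.constraints)
            violations_after = len(final) - len(recheck)
        else:
            violations_after = 0

    if len(final) < 100:
        raise TooFewSurvivorsError(
            f"only {len(final)} rows survived cleaning; increase n_records "
            f"({plan.n_records}) or loosen constraints")

    realized = spearman_matrix(final)
    moment_comparison = {
        c: {"fitted_mean": marginals[c].mean(), "realized_mean": float(final[c].mean()),
            "fitted_var": marginals[c].var(), "realized_var": float(final[c].var())}
        for c in plan.target.columns}
    manifest = {
        "seed": plan.seed,
        "column_seeds": col_seeds,
        "imposition_seed": impose_seed,
        "mode": plan.mode,
        "order": plan.order,
        "n_records": plan.n_records,
        "final_n": len(final),
        "removals": removal_log,
        "violations_after_imposition": violations_after,
        "marginal_families": {c: marginals[c].family for c in plan.target.columns},
        "realized_spearman": {"columns": list(realized.columns),
                              "matrix": realized.matrix.tolist()},
        "moment_comparison": moment_comparison,
    }
    return final, manifest


def realized_correlation_report(before: SpearmanTarget, after: pd.DataFrame
                                ) -> CorrelationDeviation:
    """Deviation of a table's realized Spearman matrix from a target."""
    if set(after.columns) != set(before.columns):
        raise ValueError("columns of the table and the target do not align")
    realized = spearman_matrix(after[list(before.columns)])
    return CorrelationDeviation(before.columns, realized.matrix - before.matrix)
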