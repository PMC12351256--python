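"""2x2 cross-testing: RF and LM fitted/evaluated across distribution types.

Builds two synthetic databases from the same source table -- one with
all-normal marginals, one with AIC-selected best-fit marginals -- fits a
random forest and a multiple linear regression on each, and evaluates every
fitted model on both databases through the adequacy statistics.
"""

from ranksynth import (SynthesisPlan, cross_test, fit_marginals_table,
                       make_methane_fixture, methane_constraints,
                       spearman_matrix, synthesize)
from ranksynth.fixtures import FixtureSpec, methane_beta_envelopes

source = make_methane_fixture(FixtureSpec(n_rows=263, seed=3))
target = spearman_matrix(source)

dbs = {}
for mode in ("normal_only", "best_fit"):
    marginals = fit_marginals_table(source, mode=mode,
                                    beta_envelopes=methane_beta_envelopes())
    plan = SynthesisPlan(n_records=6000, target=target,
                         constraints=methane_constraints(), mode=mode, seed=4)
    dbs[mode], _ = synthesize(marginals, plan)

grid = cross_test(dbs["normal_only"], dbs["best_fit"], "CH4", seed=5)
for (train, evaluate, model), rep in sorted(grid.cells.items()):
    tag = "same " if train == evaluate else "cross"
    print(f"{model} trained on {train:>9}, evaluated on {evaluate:>9} "
          f"({tag}): r2adj={rep.r2_adj:.3f}  MB={rep.mb:+.2f} g/d  "
          f"MSEP={rep.msep:.0f}")

print("\nReading: the forest explains more variance than the linear model "
      "inside its own distribution but loses accuracy (higher MSEP) when the "
      "evaluation database follows different marginals; the linear model's "
      "error barely moves across the grid.")
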