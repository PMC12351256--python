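"""Forest importance indices: PAS (accuracy) and SER (tree structure).

Fits the default forest (150 trees, 4 candidate variables per split) to the
methane stand-in table plus one pure-noise column and prints both importance
indices, sorted the way importance plots are usually laid out (descending
SER).
"""

import numpy as np

from ranksynth import fit_rf, importance, make_methane_fixture
from ranksynth.fixtures import FixtureSpec

table = make_methane_fixture(FixtureSpec(n_rows=800, seed=6))
table = table.assign(noise=np.random.default_rng(7).standard_normal(len(table)))

model = fit_rf(table, "CH4", seed=8)
report = importance(model, seed=8)

print("variable   PAS (% OOB-MSE increase)   SER ((g/d)^2)")
for var, row in report.ranked().iterrows():
    print(f"{var:>8}   {row['pas']:24.2f}   {row['ser']:13.0f}")

print("\nPAS: how much the out-of-bag error grows when a variable's values "
      "are shuffled -- predictive relevance.")
print("SER: how much residual sum of squares the variable's splits remove -- "
      "its role in the tree structure.")
print(f"The intake analogue dominates ({report.pas.idxmax()} has the top "
      f"PAS) and the pure-noise column sits near zero "
      f"({report.pas['noise']:+.2f}%).")
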