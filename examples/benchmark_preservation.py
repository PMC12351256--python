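"""Moment/correlation preservation benchmark: rank method vs copula.

Repeats the imposition experiment (chi-square(2), beta(2,5), log-normal(0,1);
5,000 samples; 100 iterations) for both methods and summarises the signed
Spearman deviation envelope and spread per variable pair.
"""

from ranksynth import run_benchmark

for method in ("rank", "copula"):
    result = run_benchmark(method, n=5000, iterations=100, seed=42)
    print(f"{method} method:")
    for pair, (lo, hi) in result.deviation_range().items():
        sd = result.deviation_sd()[pair]
        print(f"  {pair[0]}-{pair[1]}: deviations in [{lo:+.4f}, {hi:+.4f}], "
              f"SD {sd:.4f}")
    print(f"  largest moment change after imposition: "
          f"{result.max_moment_gap():.2e}")
    if method == "copula":
        bad = sum(not c for c in result.converged)
        print(f"  non-converged iterations: {bad}")
    print()

print("Both methods leave every marginal moment untouched (the outputs are "
      "permutations of the inputs); the deviation envelopes show how "
      "faithfully each reproduces the target rank correlations.")
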