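import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ranksynth.benchmark import default_benchmark_marginals, default_benchmark_target
from ranksynth.rank_correlate import (SpearmanTarget, cholesky_factor,
                                      copula_impose, correlated_normal_scores,
                                      impose_rank_correlation, spearman_matrix,
                                      spearman_to_pearson)


def three_dist_table(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({c: f(n, rng)
                         for c, f in default_benchmark_marginals().items()})


class TestSpearmanTarget:
    def test_entries_outside_unit_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            SpearmanTarget(("a", "b"), np.array([[1.0, 1.2], [1.2, 1.0]]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SpearmanTarget(("a", "b"), np.array([[1.0, 0.3], [0.5, 1.0]]))

    def test_indefinite_rejected(self):
        m = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="semi-definite"):
            SpearmanTarget(("a", "b", "c"), m)

    def test_comonotone_pair_admitted(self):
        # exact rho = 1 is singular but valid as a target
        t = SpearmanTarget(("a", "b"), np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert t.matrix[0, 1] == 1.0


class TestCholesky:
    def test_identity(self):
        t = SpearmanTarget.identity(("a", "b", "c"))
        assert np.array_equal(cholesky_factor(t), np.eye(3))

    def test_two_by_two_half(self):
        t = SpearmanTarget.from_pairs(("a", "b"), {("a", "b"): 0.5})
        L = cholesky_factor(t)
        assert L[1] == pytest.approx([0.5, np.sqrt(0.75)])
        assert np.allclose(L @ L.T, t.matrix, atol=1e-10)

    def test_singular_names_failing_minor(self):
        t = SpearmanTarget(("a", "b"), np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="order 2"):
            cholesky_factor(t)


class TestNormalScores:
    def test_identity_target_uncorrelated(self):
        t = SpearmanTarget.identity(("a", "b", "c"))
        z = correlated_normal_scores(10_000, t, seed=5)
        c = np.corrcoef(z.to_numpy(), rowvar=False)
        off = c[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.04)  # 3/sqrt(n) scale

    def test_reproducible(self):
        t = default_benchmark_target()
        a = correlated_normal_scores(100, t, seed=9)
        b = correlated_normal_scores(100, t, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_single_column(self):
        z = correlated_normal_scores(500, SpearmanTarget.identity(("x",)), seed=1)
        assert list(z.columns) == ["x"] and len(z) == 500

    def test_spearman_to_pearson_endpoints(self):
        assert spearman_to_pearson(0.0) == 0.0
        assert spearman_to_pearson(1.0) == pytest.approx(1.0)
        assert spearman_to_pearson(-1.0) == pytest.approx(-1.0)


class TestImposeRankCorrelation:
    def test_output_is_column_permutation(self):
        data = three_dist_table(2000, seed=3)
        out = impose_rank_correlation(data, default_benchmark_target(), seed=4)
        for c in data.columns:
            assert np.array_equal(np.sort(out[c].to_numpy()),
                                  np.sort(data[c].to_numpy()))

    def test_identity_target_preserves_moments_exactly(self):
        data = three_dist_table(1000, seed=6)
        t = SpearmanTarget.identity(tuple(data.columns))
        out = impose_rank_correlation(data, t, seed=7)
        for c in data.columns:
            s_in, s_out = np.sort(data[c].to_numpy()), np.sort(out[c].to_numpy())
            assert np.array_equal(s_in, s_out)  # bitwise, hence all moments

    def test_comonotone_target_gives_rank_one(self, rng):
        x = rng.lognormal(0, 1, 400)
        data = pd.DataFrame({"a": x, "b": x.copy()})
        t = SpearmanTarget(("a", "b"), np.array([[1.0, 1.0], [1.0, 1.0]]))
        out = impose_rank_correlation(data, t, seed=2)
        assert spearman_matrix(out).matrix[0, 1] == pytest.approx(1.0)

    def test_realized_close_to_target(self):
        data = three_dist_table(5000, seed=8)
        out = impose_rank_correlation(data, default_benchmark_target(), seed=9)
        dev = spearman_matrix(out).matrix - default_benchmark_target().matrix
        assert np.max(np.abs(dev)) < 0.05

    def test_column_mismatch_lists_names(self):
        data = three_dist_table(100, seed=1).rename(columns={"var3": "other"})
        with pytest.raises(ValueError, match="var3"):
            impose_rank_correlation(data, default_benchmark_target(), seed=0)

    def test_monotone_transform_commutes(self, rng):
        # Spearman is rank-based: imposing then log-transforming a positive
        # column equals transforming first (same seed, same ranks).
        data = three_dist_table(800, seed=12)
        t = default_benchmark_target()
        a = impose_rank_correlation(data, t, seed=13)
        logged = data.assign(var3=np.log(data["var3"]))
        b = impose_rank_correlation(logged, t, seed=13)
        assert np.allclose(np.log(a["var3"].to_numpy()), b["var3"].to_numpy())
        assert np.allclose(spearman_matrix(a).matrix, spearman_matrix(b).matrix)

    def test_normal_marginals_pearson_matches_spearman_target(self, rng):
        # special case: with all-normal columns the realized Pearson and the
        # Spearman target agree within sampling error
        data = pd.DataFrame(rng.standard_normal((4000, 3)),
                            columns=["var1", "var2", "var3"])
        t = default_benchmark_target()
        out = impose_rank_correlation(data, t, seed=3)
        pearson = np.corrcoef(out.to_numpy(), rowvar=False)
        assert np.max(np.abs(pearson - t.matrix)) < 0.05


class TestSpearmanMatrix:
    def test_monotone_cube_gives_one(self):
        x = np.linspace(-3, 3, 50)
        m = spearman_matrix(pd.DataFrame({"x": x, "y": x ** 3}))
        assert m.matrix[0, 1] == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        m = spearman_matrix(pd.DataFrame({"x": [1, 2, 3, 4], "y": [4, 3, 2, 1]}))
        assert m.matrix[0, 1] == pytest.approx(-1.0)

    def test_toy_half(self, toys):
        # brute-force oracle: ranks (1,2,3) vs (2,1,3), Pearson of ranks = 1/2
        m = spearman_matrix(toys["spearman_toy"])
        assert m.matrix[0, 1] == pytest.approx(0.5)

    def test_constant_column_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_matrix(pd.DataFrame({"x": [1, 2, 3], "y": [5, 5, 5]}))


class TestCopula:
    def test_identity_target_converges_fast_and_preserves_marginals(self):
        data = three_dist_table(4000, seed=20)
        t = SpearmanTarget.identity(tuple(data.columns))
        res = copula_impose(data, t, tol=0.05, seed=21)
        assert res.converged and res.iterations <= 3
        for c in data.columns:
            assert np.array_equal(np.sort(res.table[c].to_numpy()),
                                  np.sort(data[c].to_numpy()))

    def test_forced_non_convergence_reported(self):
        data = three_dist_table(500, seed=22)
        res = copula_impose(data, default_benchmark_target(), max_iter=1,
                            tol=1e-9, seed=23)
        assert not res.converged
        assert res.deviation.max_abs > 1e-9

    def test_output_is_column_permutation(self):
        data = three_dist_table(1500, seed=24)
        res = copula_impose(data, default_benchmark_target(), seed=25)
        for c in data.columns:
            assert np.array_equal(np.sort(res.table[c].to_numpy()),
                                  np.sort(data[c].to_numpy()))

    def test_handles_ties_deterministically(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"var1": np.round(rng.chisquare(2, 600), 1),
                             "var2": rng.beta(2, 5, 600),
                             "var3": rng.lognormal(0, 1, 600)})
        r1 = copula_impose(data, default_benchmark_target(), seed=5)
        r2 = copula_impose(data, default_benchmark_target(), seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)


@given(st.integers(min_value=0, max_value=10_000))
def test_imposition_always_permutes(seed):
    """Property: for any seed, every output column is a permutation of its
    input column (exact marginal preservation)."""
    data = three_dist_table(200, seed=seed)
    out = impose_rank_correlation(data, default_benchmark_target(), seed=seed)
    for c in data.columns:
        assert np.array_equal(np.sort(out[c].to_numpy()),
                              np.sort(data[c].to_numpy()))
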