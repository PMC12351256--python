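import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from ranksynth.marginals import (FAMILY_CATALOG, FitError, SupportError,
                                 best_fit, fit_marginal, fit_marginals_table,
                                 manifest_from_json, manifest_to_json,
                                 sample_marginal)


class TestFitMarginal:
    def test_normal_is_closed_form_gaussian_mle(self, rng):
        x = rng.gamma(3, 2, size=200)  # any fixed vector
        m = fit_marginal(x, "normal")
        assert m.params == pytest.approx((x.mean(), x.std()))  # 1/n SD

    def test_lognormal_matches_log_scale_mle(self, rng):
        x = rng.lognormal(0.0, 1.0, size=5000)
        m = fit_marginal(x, "lognormal")
        # oracle: Gaussian MLE on the log values
        assert m.params == pytest.approx((np.log(x).mean(), np.log(x).std()))
        assert abs(m.params[0]) < 0.05 and abs(m.params[1] - 1.0) < 0.05

    def test_gamma_recovers_chisquare_equivalence(self, rng):
        # chi-square(2) is exactly gamma(shape=1, scale=2)
        x = rng.chisquare(2, size=5000)
        m = fit_marginal(x, "gamma")
        assert m.params[0] == pytest.approx(1.0, abs=0.08)
        assert m.params[1] == pytest.approx(2.0, abs=0.2)

    def test_aic_identity(self, rng):
        x = rng.lognormal(1.0, 0.5, size=500)
        for family in ("normal", "lognormal", "gamma", "weibull", "exponential"):
            m = fit_marginal(x, family)
            k = FAMILY_CATALOG[family].n_free
            assert m.aic == pytest.approx(2 * k - 2 * m.log_likelihood, rel=1e-12)

    def test_density_integrates_to_one(self, rng):
        x = rng.gamma(4, 3, size=800)
        for family in ("normal", "gamma", "lognormal", "weibull"):
            m = fit_marginal(x, family)
            lo, hi = m.support
            total, _ = quad(m.pdf, max(lo, -np.inf), hi if np.isfinite(hi)
                            else np.inf, limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_refit_recovers_parameters(self):
        m = fit_marginal(np.random.default_rng(0).gamma(5, 2, 2000), "gamma")
        resampled = sample_marginal(m, 20000, seed=1)
        m2 = fit_marginal(resampled, "gamma")
        assert np.allclose(m2.params, m.params, rtol=0.1)

    def test_support_violation_names_column_and_family(self):
        with pytest.raises(SupportError, match="CH4.*lognormal"):
            fit_marginal(np.linspace(-1, 5, 50), "lognormal", column="CH4")

    def test_zero_variance_rejected_at_fit_time(self):
        with pytest.raises(FitError, match="zero variance"):
            fit_marginal(np.full(20, 3.0), "normal")

    def test_beta_requires_declared_envelope_outside_unit_interval(self, rng):
        pct = rng.beta(5, 15, 300) * 100
        with pytest.raises(SupportError, match="envelope"):
            fit_marginal(pct, "beta")
        m = fit_marginal(pct, "beta", envelope=(0, 100))
        assert m.params[2:] == (0.0, 100.0)
        assert m.support == (0.0, 100.0)
        assert m.mean() == pytest.approx(pct.mean(), rel=0.05)

    @pytest.mark.parametrize("family", list(FAMILY_CATALOG))
    def test_quantile_cdf_roundtrip(self, family, rng):
        data = {
            "beta": rng.beta(2, 5, 400),
            "triangular": rng.triangular(0, 3, 10, 400),
        }.get(family, rng.lognormal(0.5, 0.4, 400))
        m = fit_marginal(data, family)
        grid = m.ppf(np.linspace(0.01, 0.99, 25))
        assert np.allclose(m.ppf(m.cdf(grid)), grid, rtol=1e-8, atol=1e-8)


class TestBestFit:
    def test_prefers_lognormal_for_lognormal_data(self, rng):
        x = rng.lognormal(0, 1, 5000)
        chosen = best_fit(x, ["normal", "lognormal"])
        # oracle: direct log-likelihood comparison of the two fits
        ll_n = fit_marginal(x, "normal").log_likelihood
        ll_ln = fit_marginal(x, "lognormal").log_likelihood
        assert ll_ln > ll_n
        assert chosen.family == "lognormal"

    def test_prefers_normal_for_normal_data(self, rng):
        x = rng.normal(10, 1, 5000)
        assert best_fit(x, ["normal", "lognormal"]).family == "normal"

    def test_single_candidate_equals_fit_marginal(self, rng):
        x = rng.normal(5, 2, 100)
        assert best_fit(x, ["normal"]) == fit_marginal(x, "normal")

    def test_infeasible_families_skipped_not_errors(self, rng):
        x = rng.normal(0, 1, 200)  # negative values exclude positive families
        chosen = best_fit(x, ["gamma", "lognormal", "normal"])
        assert chosen.family == "normal"

    def test_all_infeasible_lists_reasons(self, rng):
        x = rng.normal(0, 1, 50)
        with pytest.raises(SupportError, match="gamma.*positive"):
            best_fit(x, ["gamma"], column="EE")

    def test_location_shift_keeps_selected_family(self, rng):
        # scale/location families only: shifting the data must not flip the pick
        x = rng.normal(0, 1, 3000)
        before = best_fit(x, ["normal", "logistic", "t", "skewnormal"]).family
        after = best_fit(x + 100.0, ["normal", "logistic", "t", "skewnormal"]).family
        assert before == after


class TestSampling:
    def test_fixed_seed_bitwise_identical(self, rng):
        m = fit_marginal(rng.gamma(2, 2, 500), "gamma")
        a = sample_marginal(m, 1000, seed=42)
        b = sample_marginal(m, 1000, seed=42)
        assert np.array_equal(a, b)

    def test_beta_sample_mean_matches_analytic(self):
        from ranksynth.fixtures import declared_marginal
        m = declared_marginal("u", "beta", (2.0, 5.0, 0.0, 1.0))
        x = sample_marginal(m, 100_000, seed=3)
        assert x.mean() == pytest.approx(2 / 7, abs=0.005)  # a/(a+b)
        assert np.all((x > 0) & (x < 1))

    def test_invalid_n(self, rng):
        m = fit_marginal(rng.normal(size=50), "normal")
        with pytest.raises(ValueError):
            sample_marginal(m, 0, seed=1)


class TestTableAndManifest:
    def test_normal_only_mode(self, methane_table):
        marginals = fit_marginals_table(methane_table, mode="normal_only")
        assert all(m.family == "normal" for m in marginals.values())

    def test_manifest_roundtrip(self, methane_table):
        from ranksynth.fixtures import methane_beta_envelopes
        marginals = fit_marginals_table(methane_table, mode="best_fit",
                                        beta_envelopes=methane_beta_envelopes())
        back = manifest_from_json(manifest_to_json(marginals))
        assert back == marginals
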