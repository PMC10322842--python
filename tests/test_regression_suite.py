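import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from navgap.regression_suite import (
    age_bands,
    fit_proportional_odds,
    gvif,
    hierarchical_f_change,
    lr_test,
    partial_eta_squared,
    predict_ordinal_proba,
    self_estimate_demographic_model,
    spearman,
)

LABELS = ("very bad", "bad", "good", "very good")


def simulate_ordinal(rng, n, beta_male=0.0, thresholds=(-1.5, -0.5, 1.0)):
    male = (rng.random(n) < 0.5).astype(float)
    latent = beta_male * male + rng.logistic(size=n)
    codes = np.searchsorted(thresholds, latent)
    return np.asarray(LABELS)[codes], pd.DataFrame({"male": male})


class TestProportionalOdds:
    def test_null_model_thresholds_are_logit_cumprops(self, rng):
        y, _ = simulate_ordinal(rng, 2000)
        fit = fit_proportional_odds(y, None)
        codes = pd.Categorical(pd.Series(y), categories=list(LABELS)).codes
        cum = np.cumsum(np.bincount(codes, minlength=4))[:3] / len(y)
        assert np.allclose(fit.thresholds, logit(cum), atol=1e-5)

    def test_planted_male_effect_recovered(self, rng):
        beta = np.log(2.0)
        y, X = simulate_ordinal(rng, 30_000, beta_male=beta)
        fit = fit_proportional_odds(y, X)
        se = 3.0 / np.sqrt(len(y))  # coarse MC scale; just sanity of magnitude
        assert fit.beta["male"] == pytest.approx(beta, abs=0.1)

    def test_probabilities_sum_to_one(self, rng):
        y, X = simulate_ordinal(rng, 500, beta_male=0.7)
        fit = fit_proportional_odds(y, X)
        proba = predict_ordinal_proba(fit, X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert (proba >= 0).all()

    def test_shift_invariance_of_probabilities(self, rng):
        """Adding a constant to all thresholds and to the linear predictor
        together leaves every category probability unchanged."""
        y, X = simulate_ordinal(rng, 400, beta_male=0.5)
        fit = fit_proportional_odds(y, X)
        p0 = predict_ordinal_proba(fit, X)
        shifted = fit.__class__(
            thresholds=fit.thresholds + 3.0,
            beta=fit.beta.copy(),
            loglik=fit.loglik,
            n=fit.n,
            categories=fit.categories,
        )
        eta = X.to_numpy() @ fit.beta.to_numpy() + 3.0
        z = shifted.thresholds[None, :] - eta[:, None]
        cum = np.concatenate(
            [np.zeros((len(eta), 1)), 1 / (1 + np.exp(-z)), np.ones((len(eta), 1))],
            axis=1,
        )
        assert np.allclose(np.diff(cum, axis=1), p0, atol=1e-12)

    def test_degenerate_single_category_errors(self):
        with pytest.raises(ValueError, match="single category"):
            fit_proportional_odds(["good"] * 50, None)

    def test_empty_category_collapsed_with_warning(self, rng):
        y = np.asarray(["bad", "good"])[(rng.random(200) < 0.5).astype(int)]
        with pytest.warns(UserWarning, match="collapsed"):
            fit = fit_proportional_odds(y, None)
        assert len(fit.thresholds) == 1


class TestLrTest:
    def test_identical_models_give_zero(self, rng):
        y, X = simulate_ordinal(rng, 300)
        full = fit_proportional_odds(y, X)
        chi2, df, p = lr_test(full, full.__class__(
            thresholds=full.thresholds, beta=full.beta.iloc[:0], loglik=full.loglik,
            n=full.n, categories=full.categories))
        assert chi2 == 0.0 and p == 1.0

    def test_different_n_rejected(self, rng):
        y1, X1 = simulate_ordinal(rng, 300)
        y2, X2 = simulate_ordinal(rng, 301)
        f1 = fit_proportional_odds(y1, X1)
        f2 = fit_proportional_odds(y2, None)
        with pytest.raises(ValueError, match="same data"):
            lr_test(f1, f2)

    def test_power_grows_with_n(self, rng):
        chis = []
        for n in (200, 2000):
            y, X = simulate_ordinal(rng, n, beta_male=0.5)
            full = fit_proportional_odds(y, X)
            null = fit_proportional_odds(y, None)
            chis.append(lr_test(full, null)[0])
        assert chis[1] > chis[0]


class TestHierarchicalF:
    def test_f_equals_t_squared_for_single_column(self, rng):
        n = 200
        X_base = pd.DataFrame({"a": rng.normal(size=n)})
        X_full = X_base.assign(b=rng.normal(size=n))
        y = 1.0 + X_base["a"] * 0.3 + X_full["b"] * 0.2 + rng.normal(size=n)
        F, df1, df2, p, dr2 = hierarchical_f_change(y, X_base, X_full)
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(X_full)).fit()
        assert F == pytest.approx(float(ols.tvalues["b"] ** 2), rel=1e-10)
        assert df1 == 1 and df2 == n - 3

    def test_null_f_distribution(self, rng):
        """Adding a pure-noise column: the F statistic follows F(1, n-p)."""
        n, reps = 60, 400
        fs = []
        for _ in range(reps):
            X_base = pd.DataFrame({"a": rng.normal(size=n)})
            X_full = X_base.assign(noise=rng.normal(size=n))
            y = X_base["a"] * 0.5 + rng.normal(size=n)
            fs.append(hierarchical_f_change(y, X_base, X_full)[0])
        ks = stats.kstest(fs, stats.f(1, n - 3).cdf)
        assert ks.pvalue > 0.01

    def test_duplicate_column_rank_deficiency(self, rng):
        X_base = pd.DataFrame({"a": rng.normal(size=50)})
        X_full = X_base.assign(dup=X_base["a"])
        with pytest.raises(ValueError, match="rank deficient"):
            hierarchical_f_change(rng.normal(size=50), X_base, X_full)

    def test_rescaling_invariance(self, rng):
        n = 100
        X_base = pd.DataFrame({"a": rng.normal(size=n)})
        X_full = X_base.assign(b=rng.normal(size=n))
        y = X_full["b"] * 0.4 + rng.normal(size=n)
        F1 = hierarchical_f_change(y, X_base, X_full)[0]
        F2 = hierarchical_f_change(y, X_base * 10.0, X_full * 10.0)[0]
        assert F1 == pytest.approx(F2, rel=1e-9)


class TestPartialEta2:
    def test_single_term_equals_r_squared(self, rng):
        n = 150
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = 0.5 * X["x"] + rng.normal(size=n)
        row = partial_eta_squared(y, X, {"x": ["x"]})[0]
        import statsmodels.api as sm

        r2 = sm.OLS(y, sm.add_constant(X)).fit().rsquared
        assert row.partial_eta2 == pytest.approx(r2, rel=1e-10)

    def test_orthogonal_balanced_design_hand_oracle(self):
        """2x2 balanced design: Type-II SS equal sequential SS and the hand
        computation."""
        a = np.array([0.0, 0, 1, 1] * 10)
        b = np.array([0.0, 1, 0, 1] * 10)
        y = 2.0 + 1.5 * a - 0.5 * b + np.linspace(-0.1, 0.1, 40)
        X = pd.DataFrame({"a": a, "b": b})
        rows = {r.term: r for r in partial_eta_squared(y, X, {"a": ["a"], "b": ["b"]})}
        n = len(y)
        rss_full, _ = np.linalg.lstsq(
            np.column_stack([np.ones(n), a, b]), y, rcond=None
        )[0:1][0], None
        # hand SS for balanced orthogonal factors
        ss_a = n / 4 * (y[a == 1].mean() - y[a == 0].mean()) ** 2
        ss_b = n / 4 * (y[b == 1].mean() - y[b == 0].mean()) ** 2
        resid = y - np.column_stack([np.ones(n), a, b]) @ np.linalg.lstsq(
            np.column_stack([np.ones(n), a, b]), y, rcond=None
        )[0]
        rss = float(resid @ resid)
        assert rows["a"].partial_eta2 == pytest.approx(ss_a / (ss_a + rss), rel=1e-8)
        assert rows["b"].partial_eta2 == pytest.approx(ss_b / (ss_b + rss), rel=1e-8)

    def test_null_term_effect_size_near_zero(self, rng):
        n = 20_000
        X = pd.DataFrame({"x": rng.normal(size=n), "noise": rng.normal(size=n)})
        y = X["x"] * 1.0 + rng.normal(size=n)
        rows = {r.term: r for r in partial_eta_squared(y, X, {"x": ["x"], "noise": ["noise"]})}
        assert rows["noise"].partial_eta2 < 0.001

    def test_terms_must_partition(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=30), "z": rng.normal(size=30)})
        with pytest.raises(ValueError, match="partition"):
            partial_eta_squared(rng.normal(size=30), X, {"x": ["x"]})


class TestGvif:
    def test_orthogonal_predictors_give_one(self, rng):
        n = 4000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        X -= X.mean()
        rows = gvif(X, {"a": ["a"], "b": ["b"], "c": ["c"]})
        for r in rows:
            assert r.gvif == pytest.approx(1.0, abs=0.02)

    def test_known_pairwise_correlation(self):
        """Two predictors with correlation r: VIF = 1/(1-r^2) = 1.5625 at r=0.6."""
        n = 10_000
        rng = np.random.default_rng(0)
        a = rng.normal(size=n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.normal(size=n)
        # force the empirical correlation to exactly 0.6 via Gram-Schmidt
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        b_orth = b - np.dot(a, b) / np.dot(a, a) * a
        b_exact = 0.6 * a + np.sqrt(1 - 0.36) * b_orth / b_orth.std()
        X = pd.DataFrame({"a": a, "b": b_exact})
        rows = gvif(X, {"a": ["a"], "b": ["b"]})
        for r in rows:
            assert r.gvif == pytest.approx(1.5625, rel=1e-6)
            assert r.gvif_scaled == pytest.approx(1.25, rel=1e-6)

    def test_categorical_term_matches_determinant_oracle(self, rng):
        n = 500
        cat = rng.integers(0, 3, size=n)
        d1 = (cat == 1).astype(float)
        d2 = (cat == 2).astype(float)
        x = rng.normal(size=n) + 0.3 * d1
        X = pd.DataFrame({"d1": d1, "d2": d2, "x": x})
        rows = {r.term: r for r in gvif(X, {"cat": ["d1", "d2"], "x": ["x"]})}
        R = np.corrcoef(X.to_numpy(), rowvar=False)
        oracle = (
            np.linalg.det(R[:2, :2]) * np.linalg.det(R[2:, 2:]) / np.linalg.det(R)
        )
        assert rows["cat"].gvif == pytest.approx(oracle, rel=1e-10)
        assert rows["cat"].df == 2
        assert rows["cat"].gvif_scaled == pytest.approx(oracle ** 0.25, rel=1e-10)

    def test_singular_matrix_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="singular"):
            gvif(X, {"a": ["a"], "b": ["b"]})


class TestSpearman:
    def test_perfect_orderings(self):
        x = np.arange(10.0)
        assert spearman(x, x**3).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=30).astype(float)
            y = rng.integers(0, 5, size=30).astype(float)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            rx = stats.rankdata(x)  # mid-ranks
            ry = stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman(x, y).rho == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, 5 * y - 2).rho == pytest.approx(base, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError, match="zero variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDemographicModel:
    def test_age_bands(self):
        bands = age_bands([19, 29, 30, 45, 59, 60, 70])
        assert list(bands) == ["19-29", "19-29", "30-39", "40-49", "50-59", "60-70", "60-70"]

    def test_planted_gender_effect_detected(self, rng):
        n = 5000
        players = pd.DataFrame(
            {
                "age": rng.integers(19, 71, size=n),
                "gender": np.where(rng.random(n) < 0.5, "male", "female"),
            }
        )
        male = (players["gender"] == "male").astype(float)
        latent = np.log(2.0) * male + rng.logistic(size=n)
        players["self_estimate"] = np.asarray(LABELS)[
            np.searchsorted([-1.5, -0.5, 1.0], latent)
        ]
        out = self_estimate_demographic_model(players)
        chi2, df, p = out["gender_lr"]
        assert df == 1 and p < 1e-6
        assert out["male_odds_ratio"] == pytest.approx(2.0, rel=0.25)
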