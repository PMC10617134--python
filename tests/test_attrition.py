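"""Multiple imputation (PMM), participation weights and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from targetmr.attrition import (
    AttritionError, compute_ipw, fit_response_model, impute_pmm, pool_rubin,
)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestImputePMM:
    def test_no_missing_cells_gives_identical_tables(self):
        df = pd.DataFrame({"x": np.arange(30.0), "y": np.arange(30.0) ** 2})
        ens = impute_pmm(df, m=3, seed=1)
        for t in ens.completed_tables:
            pd.testing.assert_frame_equal(t, df)

    def test_observed_cells_identical_across_imputations(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.standard_normal(100),
                           "y": rng.standard_normal(100)})
        df.loc[rng.random(100) < 0.3, "y"] = np.nan
        obs = df["y"].notna()
        ens = impute_pmm(df, m=4, seed=2, predictors=["x"])
        for t in ens.completed_tables:
            assert np.allclose(t.loc[obs, "y"], df.loc[obs, "y"])
            assert t["y"].notna().all()

    def test_binary_variable_keeps_donor_support(self):
        rng = np.random.default_rng(3)
        n = 200
        x = rng.standard_normal(n)
        y = (x + rng.standard_normal(n) > 0).astype(float)
        df = pd.DataFrame({"x": x, "y": y})
        df.loc[rng.random(n) < 0.25, "y"] = np.nan
        ens = impute_pmm(df, m=5, seed=3, predictors=["x"])
        for t in ens.completed_tables:
            assert set(np.unique(t["y"])) <= {0.0, 1.0}

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.standard_normal(80), "y": rng.standard_normal(80)})
        df.loc[rng.random(80) < 0.3, "y"] = np.nan
        a = impute_pmm(df, m=3, seed=9, predictors=["x"])
        b = impute_pmm(df, m=3, seed=9, predictors=["x"])
        for ta, tb in zip(a.completed_tables, b.completed_tables):
            pd.testing.assert_frame_equal(ta, tb)

    def test_too_few_donors_names_variable(self):
        df = pd.DataFrame({"x": np.arange(30.0), "bad": [1.0] * 10 + [np.nan] * 20})
        with pytest.raises(AttritionError, match="bad"):
            impute_pmm(df, m=2, seed=0, predictors=["x"])

    def test_mar_imputation_reduces_bias_vs_complete_case(self):
        """Under MAR-on-auxiliary missingness the pooled imputation slope
        beats the complete-case slope in most replicates."""
        wins = 0
        n_seeds = 60
        theta = 0.5
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            n = 900
            x = rng.standard_normal(n)
            u = rng.standard_normal(n)
            y = theta * x + 0.8 * u + 0.5 * rng.standard_normal(n)
            aux = u + 0.3 * rng.standard_normal(n)
            keep = rng.random(n) < _expit(0.6 + 1.5 * x * np.sign(aux) + 1.2 * aux)
            df = pd.DataFrame({"x": x, "aux": aux, "y": np.where(keep, y, np.nan)})
            ens = impute_pmm(df, m=5, seed=seed, predictors=["x", "aux"])
            est = []
            for t in ens.completed_tables:
                est.append(np.polyfit(t["x"], t["y"], 1)[0])
            mi = float(np.mean(est))
            cc = np.polyfit(df.loc[keep, "x"], df.loc[keep, "y"], 1)[0]
            wins += abs(mi - theta) < abs(cc - theta)
        assert wins >= int(0.8 * n_seeds)


class TestResponseModel:
    def _cohort(self, n=50_000, seed=5):
        rng = np.random.default_rng(seed)
        age = rng.standard_normal(n)
        sex = rng.integers(0, 2, n).astype(float)
        eta = 0.8 - 0.5 * age + 0.3 * sex
        responded = (rng.random(n) < _expit(eta)).astype(int)
        return pd.DataFrame({"age": age, "sex": sex, "responded": responded})

    def test_planted_coefficients_recovered(self):
        import statsmodels.api as sm
        df = self._cohort()
        X = sm.add_constant(df[["age", "sex"]].to_numpy())
        fit = sm.Logit(df["responded"], X).fit(disp=0)
        truth = np.array([0.8, -0.5, 0.3])
        assert np.all(np.abs(fit.params - truth) < 3 * fit.bse)
        p = fit_response_model(df, ["age", "sex"])
        assert ((p > 0) & (p < 1)).all()

    def test_constant_predictors_reduce_to_response_rate(self):
        df = self._cohort(n=2000)
        df["const1"] = 1.0
        p = fit_response_model(df, ["const1"])
        assert np.allclose(p, df["responded"].mean(), atol=1e-8)

    def test_degenerate_response_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0), "responded": np.ones(10, int)})
        with pytest.raises(AttritionError):
            fit_response_model(df, ["x"])

    def test_separation_detected(self):
        n = 500
        x = np.linspace(-3, 3, n)
        df = pd.DataFrame({"x": x, "responded": (x > 0).astype(int)})
        with pytest.raises(AttritionError, match="separat"):
            fit_response_model(df, ["x"])


class TestIPW:
    def test_constant_probability_gives_unit_weights(self):
        w = compute_ipw(pd.Series([0.5] * 10))
        assert np.allclose(w, 1.0)

    def test_truncation_only_affects_tails(self):
        rng = np.random.default_rng(6)
        p = pd.Series(rng.uniform(0.02, 0.98, 2000))
        w_t = compute_ipw(p, truncation=(1, 99))
        w_f = compute_ipw(p, truncation=None)
        raw = 1.0 / p
        lo, hi = np.percentile(raw, [1, 99])
        inner = (raw > lo) & (raw < hi)
        # interior weights agree up to the normalization constant
        ratio = (w_t[inner] / w_f[inner]).to_numpy()
        assert np.allclose(ratio, ratio[0])

    def test_weights_balance_covariates_under_correct_model(self):
        rng = np.random.default_rng(7)
        n = 40_000
        x = rng.standard_normal(n)
        p = _expit(0.5 + 1.0 * x)
        resp = rng.random(n) < p
        w = compute_ipw(pd.Series(p), responded=resp, truncation=None)
        # responders are selected on x, but weighting restores the mean
        naive = x[resp].mean()
        weighted = np.average(x[resp], weights=w[resp])
        assert abs(naive) > 0.1
        assert weighted == pytest.approx(0.0, abs=0.03)

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(AttritionError):
            compute_ipw(pd.Series([0.0, 0.5]))


class TestRubin:
    def test_toy_arithmetic(self):
        res = pool_rubin([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert res.estimate == pytest.approx(2.0)
        assert res.within_var == pytest.approx(1.0)
        assert res.between_var == pytest.approx(1.0)
        assert res.total_var == pytest.approx(2.0 + 1.0 / 3.0, abs=1e-9)
        assert res.se == pytest.approx(np.sqrt(7 / 3), abs=1e-9)

    def test_identical_imputations_collapse_to_within_variance(self):
        res = pool_rubin([1.5] * 5, [0.04] * 5)
        assert res.between_var == 0.0
        assert res.se == pytest.approx(0.2)

    def test_df_matches_textbook_oracle(self):
        """Barnard-Rubin df identical to an independent implementation."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            m = int(rng.integers(2, 30))
            q = rng.standard_normal(m)
            v = rng.uniform(0.5, 2.0, m)
            df_com = float(rng.integers(20, 5000))
            res = pool_rubin(q, v, df_com=df_com)
            w = v.mean()
            b = q.var(ddof=1)
            t = w + (1 + 1 / m) * b
            lam = (1 + 1 / m) * b / t
            nu_old = (m - 1) / lam**2
            nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            expect = 1 / (1 / nu_old + 1 / nu_obs)
            assert res.df == pytest.approx(expect, rel=1e-12)

    def test_pooling_invariant_to_imputation_order(self):
        rng = np.random.default_rng(9)
        q = rng.standard_normal(10)
        v = rng.uniform(0.5, 1.5, 10)
        a = pool_rubin(q, v)
        perm = rng.permutation(10)
        b = pool_rubin(q[perm], v[perm])
        assert a.estimate == pytest.approx(b.estimate)
        assert a.se == pytest.approx(b.se)
        assert a.df == pytest.approx(b.df)

    def test_single_imputation_rejected(self):
        with pytest.raises(AttritionError):
            pool_rubin([1.0], [1.0])


def test_mcar_missingness_agrees_with_complete_case():
    """Under MCAR the MI+IPW machinery introduces no bias: pooled and
    complete-case slopes agree within Monte-Carlo error."""
    diffs = []
    for s in range(30):
        rng = np.random.default_rng(700 + s)
        n = 3000
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        miss = rng.random(n) < 0.3
        df = pd.DataFrame({"x": x, "z": rng.standard_normal(n),
                           "responded": (~miss).astype(int),
                           "y": np.where(miss, np.nan, y)})
        cc = np.polyfit(df.dropna()["x"], df.dropna()["y"], 1)[0]
        p = fit_response_model(df, ["x", "z"])
        w = compute_ipw(p, df["responded"])
        resp = df[df["responded"] == 1]
        wr = w[df["responded"] == 1].to_numpy()
        ens = impute_pmm(resp.copy(), m=5, seed=s, predictors=["x", "z"], targets=["y"])
        est = []
        for t in ens.completed_tables:
            X = np.column_stack([np.ones(len(t)), t["x"]])
            Xw = X * wr[:, None]
            est.append(np.linalg.solve(X.T @ Xw, Xw.T @ t["y"].to_numpy())[1])
        diffs.append(np.mean(est) - cc)
    assert abs(np.mean(diffs)) < 0.01


def test_low_missingness_converges_to_complete_case():
    """At 0.1% missingness the MI pipeline agrees with complete case."""
    rng = np.random.default_rng(11)
    n = 5000
    x = rng.standard_normal(n)
    y = 0.4 * x + rng.standard_normal(n)
    df = pd.DataFrame({"x": x, "y": y})
    df.loc[rng.choice(n, size=5, replace=False), "y"] = np.nan
    ens = impute_pmm(df, m=10, seed=12, predictors=["x"])
    slopes = [np.polyfit(t["x"], t["y"], 1)[0] for t in ens.completed_tables]
    cc = np.polyfit(df.dropna()["x"], df.dropna()["y"], 1)[0]
    assert np.mean(slopes) == pytest.approx(cc, rel=0.02)
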