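"""Meta-analysis: hand-computed oracles and cross-checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pubertwin.meta import (EFFECT_FILTER, STRICT_P, SUGGESTIVE_P,
                            benjamini_hochberg, cochran_q, fixed_effect_meta,
                            random_effect_meta, run_meta_pipeline,
                            t_to_partial_r)


class TestPartialR:
    def test_hand_value(self):
        # t = 2 on df = 4: r = 2 / sqrt(4 + 4) = 0.7071...
        r, var = t_to_partial_r(2.0, n=6, p_count=2)
        assert r == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert var == pytest.approx((1 - 0.5) ** 2 / 4, abs=1e-12)

    def test_matches_regression_partial_correlation(self):
        # oracle: residualize both y and x on covariates and correlate
        rng = np.random.default_rng(60)
        n = 200
        z = rng.standard_normal((n, 2))
        x = z[:, 0] * 0.5 + rng.standard_normal(n)
        y = 0.3 * x + z @ [0.4, -0.2] + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, z])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        df = n - X.shape[1]
        s2 = resid @ resid / df
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t = coef[1] / se
        r, _ = t_to_partial_r(t, n=n, p_count=X.shape[1])
        C = np.column_stack([np.ones(n), z])
        ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
        rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
        oracle = np.corrcoef(ry, rx)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_zero_df_rejected_and_infinite_t_saturates(self):
        with pytest.raises(ValueError, match="df"):
            t_to_partial_r(1.0, n=2, p_count=2)
        r, var = t_to_partial_r(np.inf, n=10, p_count=2)
        assert (r, var) == (1.0, 0.0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(t=st.floats(-50, 50), df=st.integers(1, 500))
    def test_odd_bounded_monotone(self, t, df):
        r, var = t_to_partial_r(t, n=df + 2, p_count=2)
        r_neg, _ = t_to_partial_r(-t, n=df + 2, p_count=2)
        assert -1 < r < 1 and var > 0
        assert r_neg == pytest.approx(-r, abs=1e-12)
        r2, _ = t_to_partial_r(t + 1.0, n=df + 2, p_count=2)
        assert r2 > r


class TestFixedRandom:
    def test_fixed_effect_hand_oracle(self):
        # effects (0.1, 0.2) with variances (0.01, 0.02):
        # weights (100, 50) -> est = (10 + 10) / 150 = 0.13333
        est, se, p = fixed_effect_meta([0.1, 0.2], [0.01, 0.02])
        assert est == pytest.approx(0.4 / 3, abs=1e-12)
        assert se == pytest.approx(np.sqrt(1 / 150), abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(est / se), abs=1e-15)

    def test_cochran_q_hand_oracle(self):
        # equal variances 0.02: est = 0.15,
        # Q = 50 * (0.05^2 + 0.05^2) = 0.25
        q, q_p = cochran_q([0.1, 0.2], [0.02, 0.02])
        assert q == pytest.approx(0.25, abs=1e-12)
        assert q_p == pytest.approx(stats.chi2.sf(0.25, 1), abs=1e-15)

    def test_random_equals_fixed_when_homogeneous(self):
        eff, var = [0.1, 0.105, 0.098], [0.02, 0.025, 0.018]
        fe = fixed_effect_meta(eff, var)
        re = random_effect_meta(eff, var)
        assert re == pytest.approx(fe, abs=1e-12)

    def test_random_widens_se_under_heterogeneity(self):
        eff, var = [0.5, -0.4], [0.005, 0.005]
        _, se_f, _ = fixed_effect_meta(eff, var)
        est_r, se_r, _ = random_effect_meta(eff, var)
        assert se_r > se_f
        # with equal variances the DL estimate is the simple mean
        assert est_r == pytest.approx(0.05, abs=1e-12)

    def test_dl_tau2_oracle(self):
        # k = 2, equal v: Q = (y1-y2)^2 / (2v); denom = 2/v - (2/v^2)/(2/v)
        # = 3/(2v); tau2 = (Q - 1) / denom
        y, v = np.array([0.5, -0.4]), np.array([0.005, 0.005])
        q, _ = cochran_q(y, v)
        tau2 = (q - 1) / (2 / 0.005 - 2 / 0.005 ** 2 / (2 / 0.005))
        wr = 1 / (v + tau2)
        est = (wr * y).sum() / wr.sum()
        se = 1 / np.sqrt(wr.sum())
        got = random_effect_meta(y, v)
        assert got[0] == pytest.approx(est, abs=1e-12)
        assert got[1] == pytest.approx(se, abs=1e-12)

    def test_rejects_bad_variances(self):
        with pytest.raises(ValueError, match="positive"):
            fixed_effect_meta([0.1, 0.2], [0.0, 0.01])

    def test_weighting_favors_precise_study(self):
        est, _, _ = fixed_effect_meta([0.0, 1.0], [1e-6, 1.0])
        assert abs(est) < 1e-3


class TestBenjaminiHochberg:
    def test_hand_oracle(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03], atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(61)
        p = rng.random(500) ** 2
        ours = benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_preserves_order_and_bounds(self):
        p = np.array([0.5, 0.001, 0.04, 1.0, 0.0])
        adj = benjamini_hochberg(p)
        assert ((0 <= adj) & (adj <= 1)).all()
        assert (np.argsort(adj, kind="stable") == np.argsort(
            p, kind="stable")).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, np.nan])


def _platform_results(t_values, n=400, p_count=10):
    return pd.DataFrame({
        "t": t_values, "n": n, "p_count": p_count,
    }, index=[f"cg{i}" for i in range(len(t_values))])


class TestMetaPipeline:
    def test_intersection_only(self):
        a = _platform_results([1.0, 2.0, 3.0])
        b = _platform_results([1.0, 2.0])
        out = run_meta_pipeline(a, b)
        assert set(out.index) == {"cg0", "cg1"}
        with pytest.raises(ValueError, match="share no CpG"):
            run_meta_pipeline(a, b.rename(index={"cg0": "x0", "cg1": "x1"}))

    def test_tiers_and_effect_filter(self):
        a = _platform_results([0.5, 5.2, 9.0], n=1500)
        b = _platform_results([0.4, 5.0, 9.5], n=1200)
        out = run_meta_pipeline(a, b)
        assert out.loc["cg0", "tier"] == "none"
        assert out.loc["cg1", "tier"] in ("suggestive", "strict")
        assert out.loc["cg2", "tier"] == "strict"
        assert out.loc["cg2", "p_value"] <= STRICT_P
        assert bool(out.loc["cg2", "passes_effect_filter"]) == \
            (abs(out.loc["cg2", "r_meta"]) > EFFECT_FILTER)
        assert not out.heterogeneous.any()
        assert (out.method == "fixed").all()

    def test_heterogeneous_cpg_switches_to_random(self):
        # one wildly discordant CpG among many concordant ones
        t_a = [0.3] * 60 + [12.0]
        t_b = [0.2] * 60 + [-12.0]
        out = run_meta_pipeline(_platform_results(t_a, n=800),
                                _platform_results(t_b, n=800))
        het = out.loc["cg60"]
        assert bool(het.heterogeneous)
        assert het.method == "random"
        # random effects near zero with wide SE for the conflicted CpG
        assert abs(het.r_meta) < 0.05
        assert het.tier == "none"
        assert (out.drop("cg60").method == "fixed").all()

    def test_null_strict_hits_rare(self):
        rng = np.random.default_rng(62)
        n_cpg = 3000
        a = _platform_results(rng.standard_normal(n_cpg), n=700)
        b = _platform_results(rng.standard_normal(n_cpg), n=700)
        out = run_meta_pipeline(a, b)
        assert (out.tier == "strict").sum() == 0
        assert (out.p_value < 0.05).mean() < 0.08

    def test_uses_moderated_column_when_asked(self):
        a = _platform_results([2.0, 3.0]).assign(t_moderated=[8.0, 9.0])
        b = _platform_results([2.0, 3.0]).assign(t_moderated=[8.0, 9.0])
        plain = run_meta_pipeline(a, b)
        mod = run_meta_pipeline(a, b, t_column="t_moderated")
        assert (mod.p_value < plain.p_value).all()
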