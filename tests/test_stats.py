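"""Inferential battery vs independent brute-force oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from oridisc.stats import (
    ThresholdMixedModel,
    bca_interval,
    gg_epsilon,
    hedges_g,
    holm_adjust,
    pairwise_contrasts,
    pearson_r,
    rm_anova_omega2,
)

from conftest import make_balanced_threshold_table


# ---------------------------------------------------------------------------
# brute-force oracles (independent, loop-based implementations)
# ---------------------------------------------------------------------------

def brute_rm_anova(matrix):
    """Naive SS decomposition of a subject x level matrix."""
    n, k = matrix.shape
    grand = sum(matrix[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(matrix[i]) / k for i in range(n)]
    col_means = [sum(matrix[:, j]) / n for j in range(k)]
    ss_subj = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_eff = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_tot = sum(
        (matrix[i][j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_tot - ss_subj - ss_eff
    ms_err = ss_err / ((n - 1) * (k - 1))
    F = (ss_eff / (k - 1)) / ms_err
    omega = (ss_eff - (k - 1) * ms_err) / (ss_tot + ss_subj / (n - 1))
    return F, omega


def brute_gg_epsilon(matrix):
    """GG epsilon from the textbook covariance formula, loops only."""
    n, k = matrix.shape
    means = [sum(matrix[:, j]) / n for j in range(k)]
    S = [
        [
            sum((matrix[i][a] - means[a]) * (matrix[i][b] - means[b])
                for i in range(n)) / (n - 1)
            for b in range(k)
        ]
        for a in range(k)
    ]
    grand = sum(S[a][b] for a in range(k) for b in range(k)) / k**2
    row = [sum(S[a][b] for b in range(k)) / k for a in range(k)]
    D = [
        [S[a][b] - row[a] - row[b] + grand for b in range(k)]
        for a in range(k)
    ]
    num = sum(D[j][j] for j in range(k)) ** 2
    den = (k - 1) * sum(D[a][b] ** 2 for a in range(k) for b in range(k))
    return max(min(num / den, 1.0), 1.0 / (k - 1))


def brute_hedges_unpaired(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    df = na + nb - 2
    return (1 - 3 / (4 * df - 1)) * (ma - mb) / sp**0.5


def brute_holm(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * p[i])
        running = max(running, val)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# rmANOVA / omega squared
# ---------------------------------------------------------------------------

class TestRmAnova:
    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(30):
            m = rng.normal(2.0, 1.0, size=(5, 3))
            tbl = pd.DataFrame(
                {
                    "subject_id": np.repeat([f"s{i}" for i in range(5)], 3),
                    "noise_scale": np.tile([0.5, 1.5, 3.0], 5),
                    "threshold_sigma_deg": m.ravel(),
                }
            )
            rep = rm_anova_omega2(tbl, within="noise_scale")
            F, omega = brute_rm_anova(m)
            assert rep.F == pytest.approx(F, abs=1e-10)
            assert rep.omega_sq == pytest.approx(omega, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        m = rng.normal(3.0, 1.0, size=(12, 3))
        long = pd.DataFrame(
            {
                "subject_id": np.repeat(range(12), 3),
                "noise_scale": np.tile([0.5, 1.5, 3.0], 12),
                "threshold_sigma_deg": m.ravel(),
            }
        )
        rep = rm_anova_omega2(long, within="noise_scale")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.rm_anova(data=long, dv="threshold_sigma_deg",
                              within="noise_scale", subject="subject_id",
                              correction=True)
        assert rep.F == pytest.approx(float(aov["F"].iloc[0]), abs=1e-8)
        assert rep.epsilon_gg == pytest.approx(float(aov["eps"].iloc[0]),
                                               abs=1e-8)
        if "p-GG-corr" in aov:
            assert rep.p == pytest.approx(float(aov["p-GG-corr"].iloc[0]),
                                          abs=1e-8)

    def test_perfect_effect_limit(self):
        base = np.array([2.0, 2.0, 2.0, 2.0])
        m = np.column_stack([base, base + 1.0, base + 2.0])
        tbl = pd.DataFrame(
            {
                "subject_id": np.repeat(list("abcd"), 3),
                "noise_scale": np.tile([1, 2, 3], 4),
                "threshold_sigma_deg": m.ravel(),
            }
        )
        rep = rm_anova_omega2(tbl, within="noise_scale")
        assert rep.omega_sq == pytest.approx(1.0, abs=1e-12)

    def test_omega_invariant_to_shift_and_scale(self, rng):
        tbl = make_balanced_threshold_table(rng)
        w1 = rm_anova_omega2(tbl, within="noise_scale").omega_sq
        t2 = tbl.assign(threshold_sigma_deg=tbl.threshold_sigma_deg * 3.7 + 11.0)
        w2 = rm_anova_omega2(t2, within="noise_scale").omega_sq
        assert w1 == pytest.approx(w2, abs=1e-10)

    def test_missing_cells_rejected(self, rng):
        tbl = make_balanced_threshold_table(rng).iloc[1:]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova_omega2(tbl, within="noise_scale")

    def test_other_factors_averaged_out_first(self, rng):
        # a second within factor must not change the one-way result computed
        # on per-subject level means
        tbl = make_balanced_threshold_table(rng, n_subjects=6)
        doubled = pd.concat(
            [tbl.assign(eccentricity_deg=0.0),
             tbl.assign(eccentricity_deg=5.0)],
            ignore_index=True,
        )
        a = rm_anova_omega2(tbl, within="noise_scale")
        b = rm_anova_omega2(doubled, within="noise_scale")
        assert a.F == pytest.approx(b.F, abs=1e-10)


class TestGgEpsilon:
    def test_two_levels_always_spherical(self, rng):
        m = rng.normal(size=(10, 2))
        assert gg_epsilon(m) == 1.0

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(30):
            m = rng.normal(size=(8, 4)) @ rng.normal(size=(4, 4))
            assert gg_epsilon(m) == pytest.approx(brute_gg_epsilon(m), abs=1e-10)

    def test_lower_bound_for_rank_one_structure(self, rng):
        # a single dominant between-level contrast drives epsilon to 1/(k-1)
        b = rng.normal(size=20)
        m = np.outer(b, [1.0, 0.0, -1.0]) + rng.normal(0, 1e-6, (20, 3))
        assert gg_epsilon(m) == pytest.approx(0.5, abs=1e-6)

    def test_bounds_respected(self, rng):
        for _ in range(20):
            m = rng.normal(size=(6, 3))
            eps = gg_epsilon(m)
            assert 0.5 <= eps <= 1.0


class TestHolm:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 9))
            mine = holm_adjust(p)
            ref = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            p = rng.uniform(size=6)
            np.testing.assert_allclose(holm_adjust(p), brute_holm(list(p)),
                                       atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=10))
    def test_adjusted_dominates_raw(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestHedgesG:
    def test_hand_computed_example(self):
        assert hedges_g([2, 4, 6], [1, 3, 5]) == pytest.approx(0.4, abs=1e-12)

    def test_equal_means_give_zero(self):
        assert hedges_g([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 1.5, rng.integers(3, 12))
            assert hedges_g(a, b) == pytest.approx(
                brute_hedges_unpaired(list(a), list(b)), abs=1e-12
            )

    def test_paired_sign_matches_mean_difference(self, rng):
        for _ in range(20):
            a = rng.normal(2, 1, 10)
            b = rng.normal(1, 1, 10)
            g = hedges_g(a, b, paired=True)
            assert np.sign(g) == np.sign(a.mean() - b.mean())

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_g([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestBca:
    def test_constant_data_collapses(self, rng):
        with pytest.warns(UserWarning):
            lo, hi = bca_interval(np.full(20, 3.3), np.mean, rng=rng)
        assert lo == hi == pytest.approx(3.3)

    def test_reduces_to_percentile_for_symmetric_case(self, rng):
        x = rng.normal(0, 1, 200)
        lo, hi = bca_interval(x, np.mean, rng=rng, n_boot=4000)
        se = x.std() / np.sqrt(len(x))
        # for a symmetric statistic z0 ~ 0 and a ~ 0, so BCa ~ normal interval
        assert lo == pytest.approx(x.mean() - 1.96 * se, abs=0.35 * se)
        assert hi == pytest.approx(x.mean() + 1.96 * se, abs=0.35 * se)

    def test_agrees_with_scipy_bootstrap(self, rng):
        x = rng.gamma(2.0, 1.0, 60)
        lo, hi = bca_interval(x, np.mean, rng=rng, n_boot=4000)
        ref = sps.bootstrap(
            (x,), np.mean, method="BCa", n_resamples=4000,
            random_state=np.random.default_rng(5), vectorized=False,
        ).confidence_interval
        scale = x.std() / np.sqrt(len(x))
        assert lo == pytest.approx(ref.low, abs=0.2 * scale)
        assert hi == pytest.approx(ref.high, abs=0.2 * scale)

    def test_interval_brackets_point_estimate(self, rng):
        x = rng.normal(5, 2, 40)
        lo, hi = bca_interval(x, np.median, rng=rng, n_boot=1000)
        assert lo <= np.median(x) <= hi


class TestPearson:
    def test_identity_and_orthogonal(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        x4 = np.array([0.0, 1.0, 2.0, 3.0])
        y4 = np.array([1.0, -1.0, -1.0, 1.0])  # quadratic contrast, orthogonal
        assert pearson_r(x4, y4)[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairwiseContrasts:
    def test_holm_family_and_signs(self, rng):
        tbl = make_balanced_threshold_table(rng, n_subjects=12,
                                            effects=(0.0, 0.8, 1.6))
        out = pairwise_contrasts(tbl, within="noise_scale")
        assert len(out) == 3
        assert (out.p_holm >= out.p_raw - 1e-15).all()
        for _, row in out.iterrows():
            assert np.sign(row.hedges_g) == np.sign(row.mean_diff)


# ---------------------------------------------------------------------------
# random-intercept mixed model
# ---------------------------------------------------------------------------

def simulate_mixed_table(rng, n_subjects=20, sigma_subject=0.4,
                         sigma_resid=0.3, age_beta=0.0):
    ages = rng.normal(32, 7, n_subjects)
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, sigma_subject)
        for s, off in ((0.5, -1.761), (1.5, -1.228), (3.0, 0.0)):
            for e in (0.0, 5.0, 10.0):
                y = (4.0 + off + 0.056 * e + age_beta * (ages[i] - 32)
                     + u + rng.normal(0, sigma_resid))
                rows.append(
                    {
                        "subject_id": f"s{i:02d}",
                        "age_years": ages[i],
                        "noise_scale": s,
                        "eccentricity_deg": e,
                        "threshold_sigma_deg": y,
                    }
                )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_closed_form_matches_profile_ml_oracle(self, rng):
        from scipy.optimize import minimize

        tbl = simulate_mixed_table(rng)
        res = ThresholdMixedModel(tbl).fit()
        X = ThresholdMixedModel(tbl).exog.to_numpy()
        y = tbl.threshold_sigma_deg.to_numpy()
        subj = pd.factorize(tbl.subject_id)[0]
        n = subj.max() + 1

        def negll(theta):
            s2w, s2b = np.exp(theta)
            ll = 0.0
            V_list = []
            # GLS beta for these variances
            XtViX = 0.0
            XtViy = 0.0
            for i in range(n):
                sel = subj == i
                k = sel.sum()
                Vi = s2w * np.eye(k) + s2b
                Vinv = np.linalg.inv(Vi)
                XtViX = XtViX + X[sel].T @ Vinv @ X[sel]
                XtViy = XtViy + X[sel].T @ Vinv @ y[sel]
                V_list.append((sel, Vi, Vinv))
            beta = np.linalg.solve(XtViX, XtViy)
            for sel, Vi, Vinv in V_list:
                r = y[sel] - X[sel] @ beta
                ll += -0.5 * (np.linalg.slogdet(Vi)[1] + r @ Vinv @ r)
            return -ll

        opt = minimize(negll, np.log([0.1, 0.1]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 2000})
        s2w, s2b = np.exp(opt.x)
        assert res.sigma2_residual == pytest.approx(s2w, abs=1e-6)
        assert res.sigma2_subject == pytest.approx(s2b, abs=1e-6)

    def test_matches_statsmodels_mixedlm_ml(self, rng):
        tbl = simulate_mixed_table(rng, n_subjects=15)
        closed = ThresholdMixedModel(tbl).fit()
        iterative = ThresholdMixedModel(tbl)._fit_ml()
        pd.testing.assert_series_equal(closed.fe_params, iterative.fe_params,
                                       atol=1e-5, rtol=0)
        assert closed.sigma2_subject == pytest.approx(
            iterative.sigma2_subject, abs=1e-4
        )
        assert closed.sigma2_residual == pytest.approx(
            iterative.sigma2_residual, abs=1e-4
        )

    def test_fixed_effects_recovered(self, rng):
        tbl = simulate_mixed_table(rng, n_subjects=40)
        res = ThresholdMixedModel(tbl).fit()
        assert res.fe_params["noise[0.5]"] == pytest.approx(
            -1.761, abs=3 * res.bse["noise[0.5]"]
        )
        assert res.fe_params["noise[1.5]"] == pytest.approx(
            -1.228, abs=3 * res.bse["noise[1.5]"]
        )
        assert res.fe_params["eccentricity"] == pytest.approx(
            0.056, abs=3 * res.bse["eccentricity"]
        )

    def test_zero_subject_variance_detected(self, rng):
        tbl = simulate_mixed_table(rng, sigma_subject=0.0)
        res = ThresholdMixedModel(tbl).fit()
        assert res.sigma2_subject < 0.02

    def test_age_covariate_reduces_subject_variance(self, rng):
        tbl = simulate_mixed_table(rng, age_beta=0.05)
        base = ThresholdMixedModel(tbl).fit()
        with_age = ThresholdMixedModel(tbl, age="age_years").fit()
        assert with_age.sigma2_subject < base.sigma2_subject

    def test_unbalanced_falls_back_with_warning(self, rng):
        tbl = simulate_mixed_table(rng, n_subjects=8).iloc[1:]
        with pytest.warns(UserWarning, match="unbalanced"):
            res = ThresholdMixedModel(tbl).fit()
        assert res.method.startswith("iterative")
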