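"""Inferential battery: within-subject ANOVA, effect sizes, bootstrap CIs,
and random-intercept variance decomposition.

The battery mirrors a standard psychophysics workflow:

* one-way repeated-measures ANOVA on thresholds with omega-squared effect
  sizes and Greenhouse-Geisser degree-of-freedom correction,
* Holm step-down adjustment over the pairwise post-hoc contrasts, each
  quantified with Hedges' g and a bias-corrected-and-accelerated (BCa)
  bootstrap interval,
* Pearson correlations for the exploratory age analyses, and
* a linear mixed model with subject-specific random intercepts decomposing
  threshold variance into task-driven fixed effects (noise contrasts against
  the high-noise reference, continuous eccentricity, optionally centred age)
  and between-subject variance ``sigma2_subject``.

Formulas (the within-subject omega-squared variant, the GG epsilon estimate,
the Hedges small-sample correction, the BCa endpoint adjustment and the
balanced-design profile-ML variance decomposition) are implemented directly
and oracle-tested against independent brute-force versions; see the test
suite.  Every stochastic routine takes an explicit numpy Generator.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, ndtri

__all__ = [
    "EffectSizeReport",
    "VarianceComponentsResults",
    "ThresholdMixedModel",
    "rm_anova_omega2",
    "gg_epsilon",
    "holm_adjust",
    "hedges_g",
    "bca_interval",
    "pearson_r",
    "pairwise_contrasts",
    "random_intercept_fit",
]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with omega squared
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EffectSizeReport:
    """One within-subject effect: F test, GG correction, omega squared."""

    effect: str
    F: float
    df_effect: float
    df_error: float
    p: float
    p_uncorrected: float
    omega_sq: float
    epsilon_gg: float
    n_subjects: int
    n_levels: int
    ci: tuple[float, float] | None = None

    def summary(self) -> str:
        out = (
            f"rmANOVA effect '{self.effect}': "
            f"F({self.df_effect:.2f}, {self.df_error:.2f}) = {self.F:.3f}, "
            f"p = {self.p:.4g} (GG eps = {self.epsilon_gg:.3f}), "
            f"omega^2 = {self.omega_sq:.3f}"
        )
        if self.ci is not None:
            out += f", 95% BCa [{self.ci[0]:.3f}, {self.ci[1]:.3f}]"
        return out


def _subject_by_level(table: pd.DataFrame, subject: str, within: str,
                      dv: str) -> pd.DataFrame:
    wide = table.pivot_table(index=subject, columns=within, values=dv,
                             aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.isna().sum().sum()
        raise ValueError(
            f"unbalanced table: {missing} missing subject x level cells "
            "(no imputation is performed)"
        )
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 within-subject levels")
    return wide


def gg_epsilon(matrix) -> float:
    """Greenhouse-Geisser epsilon-hat from a subject x level matrix.

    Computed from the double-centred sample covariance of the levels;
    clamped to ``[1/(k-1), 1]``.  Two levels are always spherical
    (epsilon = 1 exactly).
    """
    m = np.asarray(matrix, dtype=float)
    k = m.shape[1]
    if k < 2:
        raise ValueError("need at least 2 levels")
    if k == 2:
        return 1.0
    S = np.cov(m, rowvar=False)
    row = S.mean(axis=1, keepdims=True)
    col = S.mean(axis=0, keepdims=True)
    Sdc = S - row - col + S.mean()
    denom = (k - 1) * float(np.sum(Sdc**2))
    if denom == 0.0:
        return 1.0
    eps = float(np.trace(Sdc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_omega2(
    table: pd.DataFrame,
    within: str,
    subject: str = "subject_id",
    dv: str = "threshold_sigma_deg",
    rng: np.random.Generator | None = None,
    n_boot: int = 2000,
    alpha: float = 0.05,
) -> EffectSizeReport:
    """One-way within-subject ANOVA with omega squared and GG correction.

    If the table has other within factors (e.g. an eccentricity column while
    testing noise), they are averaged out per subject x level first, via the
    pivot's mean aggregation.  The effect size is the within-subject omega
    squared::

        omega^2 = (SS_effect - df_effect * MS_error) / (SS_total + MS_subject)

    The GG-corrected p-value is reported whenever epsilon-hat < 1
    (always-on, conservative).  With an ``rng``, a BCa interval for omega
    squared is computed by resampling subjects.
    """
    wide = _subject_by_level(table, subject, within, dv)
    m = wide.to_numpy()

    def _decompose(mat):
        n, k = mat.shape
        grand = mat.mean()
        ss_subject = k * np.sum((mat.mean(axis=1) - grand) ** 2)
        ss_effect = n * np.sum((mat.mean(axis=0) - grand) ** 2)
        ss_total = np.sum((mat - grand) ** 2)
        ss_error = ss_total - ss_subject - ss_effect
        df_effect = k - 1
        df_error = (n - 1) * (k - 1)
        ms_error = ss_error / df_error
        ms_subject = ss_subject / (n - 1)
        F = (ss_effect / df_effect) / ms_error if ms_error > 0 else np.inf
        omega = (ss_effect - df_effect * ms_error) / (ss_total + ms_subject)
        return F, df_effect, df_error, omega

    F, df1, df2, omega = _decompose(m)
    eps = gg_epsilon(m)
    p_unc = float(sps.f.sf(F, df1, df2))
    p = float(sps.f.sf(F, df1 * eps, df2 * eps)) if eps < 1 else p_unc

    ci = None
    if rng is not None:
        ci = bca_interval(
            m, lambda mat: _decompose(mat)[3], n_boot=n_boot, rng=rng,
            alpha=alpha,
        )
    return EffectSizeReport(
        effect=within,
        F=float(F),
        df_effect=float(df1 * eps) if eps < 1 else float(df1),
        df_error=float(df2 * eps) if eps < 1 else float(df2),
        p=p,
        p_uncorrected=p_unc,
        omega_sq=float(omega),
        epsilon_gg=eps,
        n_subjects=m.shape[0],
        n_levels=m.shape[1],
        ci=ci,
    )


# ---------------------------------------------------------------------------
# multiple comparisons and standardized effect sizes
# ---------------------------------------------------------------------------

def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    Sort ascending, multiply the i-th smallest by ``m - i``, enforce the
    running maximum, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def hedges_g(group_a, group_b, paired: bool = False) -> float:
    """Hedges' g: standardized mean difference with small-sample correction.

    Unpaired: pooled-SD standardizer with ``df = n_a + n_b - 2``.  Paired:
    the standardizer is the pooled across-condition SD
    ``sqrt((s_a^2 + s_b^2) / 2)`` (not the difference-score SD), with
    ``df = 2 (n - 1)`` for the correction factor ``J = 1 - 3 / (4 df - 1)``;
    g magnitudes are then on the same between-condition scale as the
    unpaired statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal length")
        n = a.size
        sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        df = 2 * (n - 1)
    else:
        na, nb = a.size, b.size
        sd = np.sqrt(
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
        df = na + nb - 2
    if sd == 0:
        raise ValueError("zero pooled SD: standardized difference undefined")
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(J * (a.mean() - b.mean()) / sd)


def bca_interval(
    data,
    statistic_fn,
    rng: np.random.Generator,
    n_boot: int = 2000,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    ``data`` is resampled along axis 0 (rows may be vectors, e.g. a subject
    x level matrix).  ``statistic_fn`` maps a resample to a scalar.  The
    bias correction ``z0`` comes from the bootstrap distribution's position
    relative to the point estimate; the acceleration ``a`` from the
    jackknife skewness.  A degenerate bootstrap distribution collapses to
    the point estimate with a warning.
    """
    if n_boot < 100:
        raise ValueError("n_boot too small for a BCa interval")
    arr = np.asarray(data, dtype=float)
    n = arr.shape[0]
    theta = float(statistic_fn(arr))
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.array([statistic_fn(arr[idx[b]]) for b in range(n_boot)], dtype=float)
    boot = boot[np.isfinite(boot)]  # degenerate resamples may be undefined
    if boot.size < n_boot // 2:
        raise ValueError("too many degenerate bootstrap resamples")
    n_boot = boot.size
    if np.ptp(boot) == 0.0:
        warnings.warn("degenerate bootstrap distribution; interval collapses "
                      "to the point estimate", stacklevel=2)
        return (theta, theta)
    prop = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / n_boot
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = ndtri(prop)
    # jackknife acceleration
    jack = np.array(
        [statistic_fn(np.delete(arr, i, axis=0)) for i in range(n)], dtype=float
    )
    jack = jack[np.isfinite(jack)]
    if jack.size < 2:
        jack = np.array([theta, theta])
    d = jack.mean() - jack
    denom = 6.0 * np.sum(d**2) ** 1.5
    a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    out = []
    for z in (ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        out.append(float(np.quantile(boot, ndtr(adj))))
    return (out[0], out[1])


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def pairwise_contrasts(
    table: pd.DataFrame,
    within: str,
    subject: str = "subject_id",
    dv: str = "threshold_sigma_deg",
    rng: np.random.Generator | None = None,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Holm-corrected paired post-hoc contrasts for one within factor.

    All level pairs are tested with paired t-tests; the Holm family is the
    set of pairwise contrasts of this factor.  Each contrast carries
    Hedges' g (paired, pooled across-condition SD) and, given an ``rng``, a
    BCa interval for g from resampling subjects.
    """
    wide = _subject_by_level(table, subject, within, dv)
    levels = list(wide.columns)
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        a = wide[la].to_numpy()
        b = wide[lb].to_numpy()
        t, p = sps.ttest_rel(a, b)
        g = hedges_g(a, b, paired=True)
        ci = None
        if rng is not None:
            pair = np.column_stack([a, b])

            def _g(m):
                try:
                    return hedges_g(m[:, 0], m[:, 1], paired=True)
                except ValueError:  # zero-SD resample at tiny n
                    return np.nan

            ci = bca_interval(pair, _g, n_boot=n_boot, rng=rng)
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "mean_diff": float(a.mean() - b.mean()),
                "t": float(t),
                "p_raw": float(p),
                "hedges_g": g,
                "ci_low": np.nan if ci is None else ci[0],
                "ci_high": np.nan if ci is None else ci[1],
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out.p_raw.to_numpy())
    return out


# ---------------------------------------------------------------------------
# random-intercept mixed model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VarianceComponentsResults:
    """Fixed effects plus variance components of the random-intercept model."""

    fe_params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigma2_subject: float
    sigma2_residual: float
    n_subjects: int
    n_obs: int
    method: str
    converged: bool = True

    def summary(self) -> str:
        lines = [
            f"Random-intercept model ({self.method}; ML)",
            f"  n subjects = {self.n_subjects}, n obs = {self.n_obs}",
            f"  sigma2_subject  = {self.sigma2_subject:.4f} "
            f"(SD = {np.sqrt(self.sigma2_subject):.3f})",
            f"  sigma2_residual = {self.sigma2_residual:.4f}",
            "  fixed effects:",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"    {name:<18} beta = {self.fe_params[name]:+.4f}  "
                f"SE = {self.bse[name]:.4f}  z = {self.zvalues[name]:+.2f}  "
                f"p = {self.pvalues[name]:.3g}"
            )
        return "\n".join(lines)


class ThresholdMixedModel:
    """Linear mixed model for cell thresholds with subject random intercepts.

    Fixed effects: indicator contrasts for the noise levels against the
    (high-noise) reference, continuous eccentricity, and optionally age
    centred on its sample mean.  For the balanced default design (every
    subject contributes the same noise x eccentricity cells) the ML solution
    is closed form: fixed effects by OLS (which equals GLS under balanced
    compound symmetry) and the variance components from the profile-ML
    decomposition of within-subject and between-subject residual sums of
    squares.  Unbalanced tables fall back to iterative ML via statsmodels
    MixedLM, with a warning.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        dv: str = "threshold_sigma_deg",
        noise: str = "noise_scale",
        ecc: str = "eccentricity_deg",
        age: str | None = None,
        reference_noise: float | None = None,
    ):
        t = table.reset_index(drop=True)
        self.dv = dv
        self.table = t
        self.subjects = t["subject_id"].to_numpy()
        levels = np.sort(t[noise].unique())
        self.reference_noise = (
            float(levels[-1]) if reference_noise is None else float(reference_noise)
        )
        cols: dict[str, np.ndarray] = {"const": np.ones(len(t))}
        for lev in levels:
            if lev == self.reference_noise:
                continue
            cols[f"noise[{lev}]"] = (t[noise] == lev).to_numpy(dtype=float)
        cols["eccentricity"] = t[ecc].to_numpy(dtype=float)
        if age is not None:
            a = t[age].to_numpy(dtype=float)
            cols["age_centered"] = a - a.mean()
        self.exog = pd.DataFrame(cols)
        self.endog = t[dv].to_numpy(dtype=float)

    # -- balance check ------------------------------------------------------
    def _is_balanced(self) -> bool:
        df = self.table.assign(_cell=list(zip(
            self.exog.get("eccentricity"),
            [tuple(self.exog[c][i] for c in self.exog.columns
                   if c.startswith("noise[")) for i in range(len(self.exog))],
        )))
        counts = df.groupby(["subject_id", "_cell"]).size().unstack(fill_value=0)
        return bool((counts.nunique() == 1).all() and (counts > 0).all().all())

    def fit(self) -> VarianceComponentsResults:
        if self._is_balanced():
            return self._fit_balanced()
        warnings.warn("unbalanced table: falling back to iterative ML",
                      stacklevel=2)
        return self._fit_ml()

    def _fit_balanced(self) -> VarianceComponentsResults:
        X = self.exog.to_numpy()
        y = self.endog
        subj, inv = np.unique(self.subjects, return_inverse=True)
        n = len(subj)
        k = len(y) // n
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        # per-subject residual means and within-subject scatter
        sums = np.bincount(inv, weights=resid, minlength=n)
        means = sums / k
        ssw = float(np.sum((resid - means[inv]) ** 2))
        sigma2_res = ssw / (n * (k - 1))
        v_hat = float(np.mean(means**2)) * k  # ML estimate of sigma2_w + k sigma2_b
        sigma2_subj = max((v_hat - sigma2_res) / k, 0.0)
        # GLS covariance of beta under the estimated compound symmetry
        # V^-1 = (1/s2w) (I - rho/(1 + k rho) J) per subject, rho = s2b/s2w
        XtViX = np.zeros((X.shape[1], X.shape[1]))
        shrink = sigma2_subj / (sigma2_res + k * sigma2_subj)
        for i in range(n):
            Xi = X[inv == i]
            XtX = Xi.T @ Xi
            xs = Xi.sum(axis=0)[:, None]
            XtViX += (XtX - shrink * (xs @ xs.T)) / sigma2_res
        cov = np.linalg.inv(XtViX)
        bse = np.sqrt(np.diag(cov))
        z = beta / bse
        p = 2.0 * (1.0 - ndtr(np.abs(z)))
        names = list(self.exog.columns)
        return VarianceComponentsResults(
            fe_params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            zvalues=pd.Series(z, index=names),
            pvalues=pd.Series(p, index=names),
            sigma2_subject=float(sigma2_subj),
            sigma2_residual=float(sigma2_res),
            n_subjects=n,
            n_obs=len(y),
            method="closed-form (balanced)",
        )

    def _fit_ml(self) -> VarianceComponentsResults:
        import statsmodels.api as sm

        model = sm.MixedLM(self.endog, self.exog, groups=self.subjects)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, method="lbfgs")
        names = list(self.exog.columns)
        fe = pd.Series(np.asarray(res.fe_params), index=names)
        bse = pd.Series(np.asarray(res.bse_fe), index=names)
        z = fe / bse
        p = pd.Series(2.0 * (1.0 - ndtr(np.abs(z))), index=names)
        return VarianceComponentsResults(
            fe_params=fe,
            bse=bse,
            zvalues=z,
            pvalues=p,
            sigma2_subject=float(res.cov_re.iloc[0, 0]),
            sigma2_residual=float(res.scale),
            n_subjects=len(np.unique(self.subjects)),
            n_obs=len(self.endog),
            method="iterative ML (statsmodels MixedLM)",
            converged=bool(res.converged),
        )


def random_intercept_fit(
    table: pd.DataFrame,
    dv: str = "threshold_sigma_deg",
    noise: str = "noise_scale",
    ecc: str = "eccentricity_deg",
    age: str | None = None,
    reference_noise: float | None = None,
) -> VarianceComponentsResults:
    """Fit the random-intercept threshold model; see :class:`ThresholdMixedModel`."""
    return ThresholdMixedModel(
        table, dv=dv, noise=noise, ecc=ecc, age=age,
        reference_noise=reference_noise,
    ).fit()
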