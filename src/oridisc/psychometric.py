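"""Maximum-likelihood cumulative-Gaussian psychometric fitting.

Trial-level clockwise/counter-clockwise responses at signed orientation
offsets are fitted with::

    P(CW | x) = (1 - lambda) * Phi((x - mu) / sigma) + lambda / 2

where ``sigma`` (the function's SD) is the threshold — the primary index of
sensitivity — ``mu`` is the response bias, and ``lambda`` a small lapse
rate, fixed at 0.02 by default (suprathreshold catch performance justifies a
small fixed lapse) or optionally free within [0, 0.1].  Fitting maximizes
the Bernoulli log-likelihood over binomially aggregated offsets with a
bounded quasi-Newton optimizer from several deterministic starting sigmas;
the best likelihood wins, ties broken toward the smallest sigma, so
refitting identical data always reproduces identical estimates.

Fits are performed on signed offsets (CW-probability form), not folded
accuracy, which preserves the meaning of the bias parameter.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .observer import CW

__all__ = [
    "PsychometricModel",
    "PsychometricResults",
    "fit_cumulative_gaussian",
    "fit_threshold_table",
    "accuracy_summary",
    "catch_trial_check",
    "plot_fit",
]

# Beyond ~2.5x the largest sampled offset the likelihood is flat in sigma,
# so estimates are capped there (and flagged) rather than left to wander.
SIGMA_BOUNDS = (0.05, 20.0)
MU_BOUNDS = (-8.0, 8.0)
LAPSE_BOUNDS = (0.0, 0.1)
SIGMA_STARTS = (0.5, 2.0, 8.0)
MIN_TRIALS = 40

_EPS = 1e-12


@dataclasses.dataclass
class PsychometricResults:
    """Fitted cumulative-Gaussian psychometric function."""

    threshold_sigma_deg: float
    bias_deg: float
    lapse_rate: float
    n_trials: int
    log_likelihood: float
    converged: bool
    lapse_free: bool
    sigma_se: float = float("nan")
    flags: tuple[str, ...] = ()
    conf_ints: dict | None = None

    def predict(self, offset_deg):
        """P(clockwise response) at the given signed offsets."""
        z = (np.asarray(offset_deg, dtype=float) - self.bias_deg) / self.threshold_sigma_deg
        p = (1.0 - self.lapse_rate) * ndtr(z) + self.lapse_rate / 2.0
        return float(p) if np.ndim(p) == 0 else p

    def summary(self) -> str:
        lines = [
            "Cumulative-Gaussian psychometric fit",
            f"  n trials        : {self.n_trials}",
            f"  threshold sigma : {self.threshold_sigma_deg:.4f} deg",
            f"  bias mu         : {self.bias_deg:.4f} deg",
            f"  lapse lambda    : {self.lapse_rate:.4f}"
            + ("" if self.lapse_free else " (fixed)"),
            f"  log-likelihood  : {self.log_likelihood:.3f}",
            f"  converged       : {self.converged}",
        ]
        if self.conf_ints:
            for k, (lo, hi) in self.conf_ints.items():
                lines.append(f"  95% CI {k:<9}: [{lo:.4f}, {hi:.4f}]")
        if self.flags:
            lines.append(f"  flags           : {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["flags"] = list(self.flags)
        return json.dumps(d)


class PsychometricModel:
    """MLE cumulative-Gaussian model for one subject x condition cell.

    Parameters
    ----------
    offsets_deg, n_trials, n_cw : array-like
        Binomially aggregated data: at each signed offset, the number of
        trials and the number of clockwise responses.
    lapse_rate : float
        Fixed lapse rate (ignored when ``free_lapse``).
    free_lapse : bool
        Fit the lapse rate within [0, 0.1] instead of fixing it.
    """

    def __init__(self, offsets_deg, n_trials, n_cw, lapse_rate: float = 0.02,
                 free_lapse: bool = False):
        self.x = np.asarray(offsets_deg, dtype=float)
        self.n = np.asarray(n_trials, dtype=float)
        self.k = np.asarray(n_cw, dtype=float)
        if not (self.x.shape == self.n.shape == self.k.shape):
            raise ValueError("offsets, trial counts and CW counts must align")
        if np.any(self.n <= 0) or np.any((self.k < 0) | (self.k > self.n)):
            raise ValueError("invalid binomial counts")
        if np.unique(np.abs(self.x)).size < 2:
            raise ValueError("need >= 2 distinct absolute offset levels")
        if not 0.0 <= lapse_rate <= 1.0:
            raise ValueError("lapse rate must lie in [0, 1]")
        self.lapse_rate = float(lapse_rate)
        self.free_lapse = bool(free_lapse)
        self.total_trials = int(self.n.sum())

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, lapse_rate: float = 0.02,
                    free_lapse: bool = False,
                    include_practice: bool = False,
                    include_catch: bool = False) -> "PsychometricModel":
        """Aggregate a trial-record table into binomial counts per offset."""
        t = trials
        if not include_practice and "is_practice" in t:
            t = t[~t.is_practice.astype(bool)]
        if not include_catch and "is_catch" in t:
            t = t[~t.is_catch.astype(bool)]
        cw = (t.response == CW).astype(int)
        agg = (
            pd.DataFrame({"offset_deg": t.offset_deg, "cw": cw})
            .groupby("offset_deg", as_index=False)
            .agg(n=("cw", "size"), k=("cw", "sum"))
        )
        return cls(agg.offset_deg, agg.n, agg.k,
                   lapse_rate=lapse_rate, free_lapse=free_lapse)

    # -- likelihood ---------------------------------------------------------
    def _prob(self, sigma, mu, lam):
        z = (self.x - mu) / sigma
        return (1.0 - lam) * ndtr(z) + lam / 2.0

    def loglike(self, params) -> float:
        if self.free_lapse:
            sigma, mu, lam = params
        else:
            (sigma, mu), lam = params, self.lapse_rate
        p = np.clip(self._prob(sigma, mu, lam), _EPS, 1.0 - _EPS)
        return float(np.sum(self.k * np.log(p) + (self.n - self.k) * np.log1p(-p)))

    def _negloglike_grad(self, params):
        if self.free_lapse:
            sigma, mu, lam = params
        else:
            (sigma, mu), lam = params, self.lapse_rate
        z = (self.x - mu) / sigma
        phi = np.exp(-0.5 * z * z) / 2.5066282746310002  # sqrt(2 pi)
        p = np.clip((1.0 - lam) * ndtr(z) + lam / 2.0, _EPS, 1.0 - _EPS)
        nll = -np.sum(self.k * np.log(p) + (self.n - self.k) * np.log1p(-p))
        w = self.k / p - (self.n - self.k) / (1.0 - p)  # d(ll)/dp
        dp_dsigma = -(1.0 - lam) * phi * z / sigma
        dp_dmu = -(1.0 - lam) * phi / sigma
        grad = [-np.sum(w * dp_dsigma), -np.sum(w * dp_dmu)]
        if self.free_lapse:
            dp_dlam = 0.5 - ndtr(z)
            grad.append(-np.sum(w * dp_dlam))
        return nll, np.asarray(grad)

    def fit(self, sigma_starts=SIGMA_STARTS) -> PsychometricResults:
        """Maximize the likelihood from multiple deterministic starts."""
        bounds = [SIGMA_BOUNDS, MU_BOUNDS]
        if self.free_lapse:
            bounds.append(LAPSE_BOUNDS)
        best = None
        any_converged = False
        for s0 in sigma_starts:
            x0 = [s0, 0.0] + ([0.02] if self.free_lapse else [])
            res = minimize(
                self._negloglike_grad, x0, jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
            )
            any_converged = any_converged or res.success
            if (
                best is None
                or res.fun < best.fun - 1e-9
                or (abs(res.fun - best.fun) <= 1e-9 and res.x[0] < best.x[0])
            ):
                best = res
        sigma, mu = float(best.x[0]), float(best.x[1])
        lam = float(best.x[2]) if self.free_lapse else self.lapse_rate
        flags = []
        if self.total_trials < MIN_TRIALS:
            flags.append("low_n")
        if sigma <= SIGMA_BOUNDS[0] * (1 + 1e-9):
            flags.append("sigma_at_lower_bound")
            warnings.warn(
                "perfect or near-perfect separation: sigma pinned at lower bound",
                stacklevel=2,
            )
        if sigma >= SIGMA_BOUNDS[1] * (1 - 1e-9):
            flags.append("sigma_at_upper_bound")
        if abs(mu) >= min(MU_BOUNDS[1], np.max(np.abs(self.x))):
            flags.append("bias_dominated")
        return PsychometricResults(
            threshold_sigma_deg=sigma,
            bias_deg=mu,
            lapse_rate=lam,
            n_trials=self.total_trials,
            log_likelihood=-float(best.fun),
            converged=bool(any_converged),
            lapse_free=self.free_lapse,
            sigma_se=self._sigma_se(sigma, mu, lam),
            flags=tuple(flags),
        )

    def _sigma_se(self, sigma: float, mu: float, lam: float) -> float:
        """Asymptotic SE of sigma-hat from the observed Fisher information."""
        z = (self.x - mu) / sigma
        phi = np.exp(-0.5 * z * z) / 2.5066282746310002
        p = np.clip((1.0 - lam) * ndtr(z) + lam / 2.0, 1e-9, 1.0 - 1e-9)
        denom = p * (1.0 - p)
        ds = (1.0 - lam) * phi * z / sigma
        dm = (1.0 - lam) * phi / sigma
        info = np.array(
            [
                [np.sum(self.n * ds * ds / denom), np.sum(self.n * ds * dm / denom)],
                [np.sum(self.n * ds * dm / denom), np.sum(self.n * dm * dm / denom)],
            ]
        )
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return float("nan")
        v = cov[0, 0]
        return float(np.sqrt(v)) if v > 0 else float("nan")

    def bootstrap_ci(self, results: PsychometricResults, rng: np.random.Generator,
                     n_boot: int = 500, alpha: float = 0.05) -> dict:
        """Parametric-bootstrap percentile CIs for (sigma, mu[, lambda])."""
        sigmas, mus = [], []
        for _ in range(n_boot):
            k_star = rng.binomial(self.n.astype(int), results.predict(self.x))
            m = PsychometricModel(self.x, self.n, k_star,
                                  lapse_rate=self.lapse_rate,
                                  free_lapse=self.free_lapse)
            r = m.fit()
            sigmas.append(r.threshold_sigma_deg)
            mus.append(r.bias_deg)
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        return {
            "threshold_sigma_deg": tuple(np.percentile(sigmas, qs)),
            "bias_deg": tuple(np.percentile(mus, qs)),
        }


def fit_cumulative_gaussian(trials: pd.DataFrame, lapse_rate: float = 0.02,
                            free_lapse: bool = False) -> PsychometricResults:
    """Fit one cell of trial records; see :class:`PsychometricModel`."""
    return PsychometricModel.from_trials(
        trials, lapse_rate=lapse_rate, free_lapse=free_lapse
    ).fit()


def fit_threshold_table(
    trials: pd.DataFrame,
    lapse_rate: float = 0.02,
    free_lapse: bool = False,
) -> pd.DataFrame:
    """Per subject x noise x eccentricity psychometric fits.

    Practice and catch trials are excluded.  Returns one row per cell with
    the threshold, bias, diagnostics and the subject's age (carried through
    for downstream between-subject analyses).
    """
    t = trials[~trials.is_practice.astype(bool) & ~trials.is_catch.astype(bool)]
    agg = (
        t.assign(cw=(t.response == CW).astype(int))
        .groupby(
            ["subject_id", "noise_scale", "eccentricity_deg", "offset_deg"],
            sort=True,
        )
        .agg(n=("cw", "size"), k=("cw", "sum"), age=("age_years", "first"))
        .reset_index()
    )
    ages = dict(zip(agg.subject_id, agg.age))
    rows = []
    for (subj, s, e), grp in agg.groupby(
        ["subject_id", "noise_scale", "eccentricity_deg"], sort=True
    ):
        res = PsychometricModel(
            grp.offset_deg.to_numpy(), grp.n.to_numpy(), grp.k.to_numpy(),
            lapse_rate=lapse_rate, free_lapse=free_lapse,
        ).fit()
        rows.append(
            {
                "subject_id": subj,
                "age_years": float(ages[subj]),
                "noise_scale": s,
                "eccentricity_deg": e,
                "threshold_sigma_deg": res.threshold_sigma_deg,
                "sigma_se": res.sigma_se,
                "bias_deg": res.bias_deg,
                "lapse_rate": res.lapse_rate,
                "n_trials": res.n_trials,
                "log_likelihood": res.log_likelihood,
                "converged": res.converged,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)


def accuracy_summary(
    trials: pd.DataFrame,
    by: str | list[str] = "noise_scale",
    rng: np.random.Generator | None = None,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Mean accuracy per group with across-subject SD and BCa 95% CI.

    Accuracy is first computed per subject (practice and catch excluded),
    then summarised across subjects — matching how group accuracy is
    conventionally reported.  CIs require an ``rng`` (they bootstrap
    subjects); without one the CI columns are NaN.
    """
    from .stats import bca_interval

    t = trials[~trials.is_practice.astype(bool) & ~trials.is_catch.astype(bool)]
    if isinstance(by, str):
        by = [by]
    rows = []
    for key, grp in t.groupby(by, sort=True):
        per_subj = grp.groupby("subject_id")["correct"].mean().to_numpy()
        if len(per_subj) == 0:
            warnings.warn(f"empty group {key}; omitted", stacklevel=2)
            continue
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n_subjects"] = len(per_subj)
        row["accuracy"] = float(per_subj.mean())
        row["sd"] = float(per_subj.std(ddof=1)) if len(per_subj) > 1 else 0.0
        if rng is not None and len(per_subj) > 1:
            lo, hi = bca_interval(per_subj, np.mean, n_boot=n_boot, rng=rng)
        else:
            lo, hi = np.nan, np.nan
        row["ci_low"], row["ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def catch_trial_check(trials: pd.DataFrame, floor: float = 0.90) -> pd.DataFrame:
    """Per-subject accuracy on suprathreshold catch trials.

    Subjects below ``floor`` are flagged for exclusion.  Raises if the table
    contains no catch trials (nothing to check engagement with).
    """
    catch = trials[trials.is_catch.astype(bool)]
    if len(catch) == 0:
        raise ValueError("no catch trials present: cannot assess engagement")
    out = (
        catch.groupby("subject_id")["correct"]
        .agg(catch_accuracy="mean", n_catch="size")
        .reset_index()
    )
    out["flagged"] = out.catch_accuracy < floor
    return out


def plot_fit(results: PsychometricResults, model: PsychometricModel | None = None,
             ax=None):
    """Plot the fitted CW-probability curve (and binned data if given)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lim = 1.2 * (np.max(np.abs(model.x)) if model is not None else 8.0)
    grid = np.linspace(-lim, lim, 201)
    ax.plot(grid, results.predict(grid), label="fit")
    if model is not None:
        ax.plot(model.x, model.k / model.n, "o", label="data")
    ax.axhline(0.5, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("orientation offset (deg, CW positive)")
    ax.set_ylabel("P(CW response)")
    ax.legend()
    return ax
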