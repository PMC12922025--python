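"""Cross-validated prediction of subject-level thresholds.

A ridge linear model predicts per-subject, per-eccentricity thresholds from
age, eccentricity, signal-to-noise efficiency and the two age interactions,
assessed with subject-grouped k-fold cross-validation against a null
baseline that predicts the training-fold mean.  Feature importance is
permutation-based: the mean drop in out-of-fold R^2 when one (standardized)
feature column is shuffled within the validation fold, normalized so the
top feature scores 1.  Grouping folds by subject keeps a subject's
eccentricity rows from straddling the train/validation split, and all
standardization statistics come from training folds only — no information
leaks from validation data into the fitted models.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

__all__ = [
    "FEATURE_COLUMNS",
    "CVResult",
    "build_feature_table",
    "kfold_cv_regression",
    "permutation_importance",
]

FEATURE_COLUMNS = ["age", "eccentricity", "efficiency", "age_x_ecc", "age_x_eff"]


def build_feature_table(
    threshold_table: pd.DataFrame,
    efficiency_tbl: pd.DataFrame,
    sigma_col: str = "threshold_sigma_deg",
) -> pd.DataFrame:
    """Join thresholds, efficiencies and ages into the prediction table.

    One row per subject x eccentricity; the target is the subject's mean
    threshold across noise levels at that eccentricity.  Interaction columns
    are formed after centring the main effects on their sample means, which
    makes them orthogonal to the main effects' means.  Zero-variance
    features and unmatched subjects are rejected with diagnostics.
    """
    target = (
        threshold_table.groupby(["subject_id", "eccentricity_deg"], as_index=False)
        .agg(threshold=(sigma_col, "mean"), age=("age_years", "first"))
    )
    eff = efficiency_tbl[["subject_id", "eccentricity_deg", "efficiency"]]
    merged = target.merge(eff, on=["subject_id", "eccentricity_deg"], how="left")
    unmatched = merged[merged.efficiency.isna()]
    if len(unmatched):
        ids = sorted(unmatched.subject_id.unique())
        raise ValueError(f"subjects without efficiency estimates: {ids}")
    out = pd.DataFrame(
        {
            "subject_id": merged.subject_id,
            "age": merged.age,
            "eccentricity": merged.eccentricity_deg,
            "efficiency": merged.efficiency,
        }
    )
    for col in ("age", "eccentricity", "efficiency"):
        if np.isclose(out[col].std(), 0.0):
            raise ValueError(f"zero-variance feature: {col}")
    age_c = out.age - out.age.mean()
    ecc_c = out.eccentricity - out.eccentricity.mean()
    eff_c = out.efficiency - out.efficiency.mean()
    out["age_x_ecc"] = age_c * ecc_c
    out["age_x_eff"] = age_c * eff_c
    out["threshold"] = merged.threshold
    return out.sort_values(["subject_id", "eccentricity"]).reset_index(drop=True)


@dataclasses.dataclass
class CVResult:
    """Grouped k-fold cross-validation metrics plus the per-fold machinery."""

    fold_r2: np.ndarray
    fold_rmse: np.ndarray
    fold_mae: np.ndarray
    baseline_r2: np.ndarray
    baseline_rmse: np.ndarray
    fold_indices: list[np.ndarray]
    models: list
    scalers: list[tuple[np.ndarray, np.ndarray]]
    k: int

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_mae))

    def metrics(self, alpha: float = 0.05) -> dict:
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]

        def block(vals):
            v = np.asarray(vals, dtype=float)
            return {
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "ci": [float(x) for x in np.percentile(v, qs)],
            }

        return {
            "k": self.k,
            "r2": block(self.fold_r2),
            "rmse_deg": block(self.fold_rmse),
            "mae_deg": block(self.fold_mae),
            "baseline_r2": block(self.baseline_r2),
            "baseline_rmse_deg": block(self.baseline_rmse),
        }

    def to_json(self) -> str:
        return json.dumps(self.metrics(), indent=2)

    def summary(self) -> str:
        m = self.metrics()
        return (
            f"{self.k}-fold grouped CV: "
            f"R^2 = {m['r2']['mean']:.3f} (SD {m['r2']['sd']:.3f}), "
            f"RMSE = {m['rmse_deg']['mean']:.3f} deg, "
            f"MAE = {m['mae_deg']['mean']:.3f} deg; "
            f"baseline R^2 = {m['baseline_r2']['mean']:.3f}"
        )


def _make_model(model: str, ridge_alpha: float, seed: int):
    if model == "ridge":
        return Ridge(alpha=ridge_alpha)
    if model == "forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def kfold_cv_regression(
    table: pd.DataFrame,
    rng: np.random.Generator,
    k: int = 10,
    model: str = "ridge",
    ridge_alpha: float = 1.0,
) -> CVResult:
    """Subject-grouped k-fold CV of the threshold predictor.

    Subjects are shuffled (seeded) and split into ``k`` groups; every row of
    a subject lands in the same fold.  Features are standardized with
    training-fold statistics, and the null baseline predicts the
    training-fold mean threshold on the identical folds.
    """
    subjects = table.subject_id.unique()
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} subject groups")
    order = rng.permutation(len(subjects))
    fold_of_subject = {
        s: f for f, chunk in enumerate(np.array_split(subjects[order], k))
        for s in chunk
    }
    folds = table.subject_id.map(fold_of_subject).to_numpy()
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = table.threshold.to_numpy(dtype=float)

    r2s, rmses, maes, base_r2s, base_rmses = [], [], [], [], []
    models, scalers, fold_indices = [], [], []
    for f in range(k):
        val = folds == f
        train = ~val
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[train] - mu) / sd
        Xval = (X[val] - mu) / sd
        est = _make_model(model, ridge_alpha, seed=int(rng.integers(2**31)))
        est.fit(Xtr, y[train])
        pred = est.predict(Xval)
        r2s.append(r2_score(y[val], pred))
        rmses.append(float(np.sqrt(mean_squared_error(y[val], pred))))
        maes.append(mean_absolute_error(y[val], pred))
        base = np.full(val.sum(), y[train].mean())
        base_r2s.append(r2_score(y[val], base))
        base_rmses.append(float(np.sqrt(mean_squared_error(y[val], base))))
        models.append(est)
        scalers.append((mu, sd))
        fold_indices.append(np.flatnonzero(val))
    return CVResult(
        fold_r2=np.asarray(r2s),
        fold_rmse=np.asarray(rmses),
        fold_mae=np.asarray(maes),
        baseline_r2=np.asarray(base_r2s),
        baseline_rmse=np.asarray(base_rmses),
        fold_indices=fold_indices,
        models=models,
        scalers=scalers,
        k=k,
    )


def permutation_importance(
    cv: CVResult,
    table: pd.DataFrame,
    rng: np.random.Generator,
    n_shuffles: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation feature importance over the stored CV folds.

    For each fitted fold model and each feature, the (standardized) feature
    column is shuffled within the validation fold ``n_shuffles`` times and
    the drop in out-of-fold R^2 recorded.  Importance is the mean drop
    normalized by the largest mean drop (the top feature scores 1.0);
    percentile CIs are taken over the fold x shuffle draws on the same
    normalized scale.
    """
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = table.threshold.to_numpy(dtype=float)
    drops = {feat: [] for feat in FEATURE_COLUMNS}
    for f, (est, (mu, sd), val_idx) in enumerate(
        zip(cv.models, cv.scalers, cv.fold_indices)
    ):
        Xval = (X[val_idx] - mu) / sd
        yval = y[val_idx]
        r2_orig = r2_score(yval, est.predict(Xval))
        for j, feat in enumerate(FEATURE_COLUMNS):
            for _ in range(n_shuffles):
                Xperm = Xval.copy()
                Xperm[:, j] = rng.permutation(Xperm[:, j])
                drops[feat].append(r2_orig - r2_score(yval, est.predict(Xperm)))
    mean_drop = {feat: float(np.mean(v)) for feat, v in drops.items()}
    top = max(mean_drop.values())
    scale = top if top > 0 else 1.0
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    rows = []
    for feat in FEATURE_COLUMNS:
        v = np.asarray(drops[feat]) / scale
        lo, hi = np.percentile(v, qs)
        rows.append(
            {
                "feature": feat,
                "raw_drop": mean_drop[feat],
                "importance": mean_drop[feat] / scale,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    out = pd.DataFrame(rows).sort_values("importance", ascending=False)
    return out.reset_index(drop=True)
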