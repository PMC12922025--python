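"""Equivalent-noise decomposition of thresholds across external-noise levels.

Under the linear-amplifier model, squared threshold grows linearly with
squared external noise::

    sigma_th^2(s) = ( sigma_int^2 + (c * s)^2 ) / E

so regressing ``sigma_th^2`` on ``(c * s)^2`` across noise levels gives the
internal noise from the intercept (``sigma_int^2 / E``) and the calculation
efficiency from the slope (``1 / E``).  The fit is ordinary (optionally
weighted) least squares in threshold-squared space — closed form, no
iterative optimizer.  Efficiency here is a derived, model-relative quantity:
values slightly above 1 can arise from sampling error or when thresholds do
not follow the linear-amplifier form exactly.

The stimulus-defined signal-to-noise ratio (|offset| / noise amplitude) is
kept as a purely descriptive bookkeeping quantity; it is fixed by the design
and is never used as an inferential predictor.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "SnrValue",
    "EquivalentNoiseModel",
    "EquivalentNoiseResults",
    "stimulus_snr",
    "fit_equivalent_noise",
    "efficiency_table",
]


@dataclasses.dataclass(frozen=True)
class SnrValue:
    """Stimulus-defined signal-to-noise ratio for one design cell."""

    offset_deg: float
    noise_amplitude: float
    ratio: float


def stimulus_snr(offset_deg: float, noise_scale: float) -> SnrValue:
    """Descriptive SNR: |orientation offset| over external-noise amplitude."""
    if noise_scale <= 0:
        raise ValueError("noise scale must be positive")
    return SnrValue(
        offset_deg=float(offset_deg),
        noise_amplitude=float(noise_scale),
        ratio=abs(float(offset_deg)) / float(noise_scale),
    )


@dataclasses.dataclass
class EquivalentNoiseResults:
    """Internal noise and efficiency inferred from one threshold-vs-noise fit."""

    internal_noise_deg: float
    efficiency: float
    slope: float
    intercept: float
    resid_ss: float
    n_noise_levels: int
    intercept_clipped: bool = False
    nonphysical_slope: bool = False

    def predict(self, noise_scale, calibration: float = 1.0):
        """Model-implied threshold (deg) at the given noise scales."""
        x = (calibration * np.asarray(noise_scale, dtype=float)) ** 2
        return np.sqrt(np.maximum(self.intercept + self.slope * x, 0.0))

    def summary(self) -> str:
        lines = [
            "Equivalent-noise fit",
            f"  noise levels used : {self.n_noise_levels}",
            f"  internal noise    : {self.internal_noise_deg:.4f} deg",
            f"  efficiency        : {self.efficiency:.4f}",
            f"  slope (1/E)       : {self.slope:.4f}",
            f"  intercept         : {self.intercept:.4f} deg^2",
            f"  residual SS       : {self.resid_ss:.3e}",
        ]
        if self.intercept_clipped:
            lines.append("  note: negative intercept clipped to 0")
        if self.nonphysical_slope:
            lines.append("  WARNING: non-positive slope; efficiency undefined")
        return "\n".join(lines)


class EquivalentNoiseModel:
    """Least-squares equivalent-noise decomposition for one observer.

    Parameters
    ----------
    thresholds_deg : array-like
        Psychometric threshold sigma at each external-noise level.
    noise_scales : array-like
        The matching external-noise scale factors (at least two distinct).
    calibration : float
        Degrees of orientation-equivalent noise per unit scale factor.
    weights : array-like, optional
        Relative weights for the threshold-squared regression (e.g. inverse
        bootstrap variances of the squared thresholds).
    """

    def __init__(self, thresholds_deg, noise_scales, calibration: float = 1.0, weights=None):
        self.thresholds = np.asarray(thresholds_deg, dtype=float)
        self.scales = np.asarray(noise_scales, dtype=float)
        if self.thresholds.shape != self.scales.shape:
            raise ValueError("thresholds and noise scales must align")
        if self.thresholds.size < 2 or np.unique(self.scales).size < 2:
            raise ValueError("need thresholds at >= 2 distinct noise levels")
        if np.any(self.thresholds <= 0):
            raise ValueError("thresholds must be positive")
        if calibration <= 0:
            raise ValueError("calibration constant must be positive")
        self.calibration = float(calibration)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    def fit(self) -> EquivalentNoiseResults:
        y = self.thresholds**2
        x = (self.calibration * self.scales) ** 2
        w = np.ones_like(x) if self.weights is None else self.weights
        sw = w.sum()
        xbar = (w * x).sum() / sw
        ybar = (w * y).sum() / sw
        sxx = (w * (x - xbar) ** 2).sum()
        slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
        intercept = ybar - slope * xbar
        resid = y - (intercept + slope * x)
        nonphysical = slope <= 0
        clipped = False
        if intercept < 0:
            intercept_eff = 0.0
            clipped = True
        else:
            intercept_eff = intercept
        if nonphysical:
            eff = np.nan
            sig_int = np.nan
        else:
            eff = 1.0 / slope
            sig_int = float(np.sqrt(intercept_eff * eff))
        return EquivalentNoiseResults(
            internal_noise_deg=sig_int,
            efficiency=eff,
            slope=float(slope),
            intercept=float(intercept),
            resid_ss=float((w * resid**2).sum()),
            n_noise_levels=int(np.unique(self.scales).size),
            intercept_clipped=clipped,
            nonphysical_slope=bool(nonphysical),
        )


def fit_equivalent_noise(
    thresholds_deg, noise_scales, calibration: float = 1.0, weights=None
) -> EquivalentNoiseResults:
    """Convenience wrapper: build and fit an :class:`EquivalentNoiseModel`."""
    return EquivalentNoiseModel(
        thresholds_deg, noise_scales, calibration=calibration, weights=weights
    ).fit()


def efficiency_table(
    threshold_table: pd.DataFrame,
    calibration: float = 1.0,
    per_eccentricity: bool = True,
    sigma_col: str = "threshold_sigma_deg",
    clip_range: tuple[float, float] = (0.05, 10.0),
    weight_by_se: bool = False,
) -> pd.DataFrame:
    """Equivalent-noise fit per subject (by default per eccentricity).

    Expects a threshold table with ``subject_id``, ``noise_scale``,
    ``eccentricity_deg`` and a threshold column.  Subjects missing any noise
    level in a stratum are skipped (recorded under the returned frame's
    ``attrs['skipped']``).  Boundary estimates — non-positive slopes, or
    efficiencies outside ``clip_range`` — are clipped into the physical
    range and flagged rather than left undefined, so downstream joins stay
    complete.  With ``weight_by_se`` and a ``sigma_se`` column, the
    regression is weighted by the inverse sampling variance of each squared
    threshold.
    """
    required = {"subject_id", "noise_scale", sigma_col}
    missing = required - set(threshold_table.columns)
    if missing:
        raise ValueError(f"threshold table lacks columns: {sorted(missing)}")
    n_levels = threshold_table["noise_scale"].nunique()
    if per_eccentricity:
        group_cols = ["subject_id", "eccentricity_deg"]
    else:
        group_cols = ["subject_id"]
    rows = []
    skipped = []
    for key, grp in threshold_table.groupby(group_cols, sort=True):
        if per_eccentricity:
            agg = grp
        else:
            # pool eccentricities: average thresholds per noise level
            agg = (
                grp.groupby("noise_scale", as_index=False)[sigma_col].mean()
            )
        if agg["noise_scale"].nunique() < n_levels:
            skipped.append(key)
            continue
        weights = None
        if weight_by_se and "sigma_se" in agg:
            var_y = (2.0 * agg[sigma_col] * agg["sigma_se"]) ** 2
            if np.all(np.isfinite(var_y)) and np.all(var_y > 0):
                weights = 1.0 / var_y.to_numpy()
        res = fit_equivalent_noise(
            agg[sigma_col].to_numpy(),
            agg["noise_scale"].to_numpy(),
            calibration=calibration,
            weights=weights,
        )
        eff = res.efficiency
        eff_clipped = False
        if res.nonphysical_slope or not np.isfinite(eff):
            eff, eff_clipped = clip_range[1], True
        elif not clip_range[0] <= eff <= clip_range[1]:
            eff, eff_clipped = float(np.clip(eff, *clip_range)), True
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            sigma_int_deg=0.0 if not np.isfinite(res.internal_noise_deg)
            else res.internal_noise_deg,
            efficiency=eff,
            resid_ss=res.resid_ss,
            intercept_clipped=res.intercept_clipped,
            nonphysical_slope=res.nonphysical_slope,
            efficiency_clipped=eff_clipped,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out
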