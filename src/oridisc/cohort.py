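"""Synthetic observer cohort with the study's between-subject structure.

The generator stands in for the unavailable human data.  Each participant's
expected threshold in a noise x eccentricity cell follows an additive
(threshold-scale) structure mirroring the mixed-effects decomposition the
analysis stage estimates::

    sigma(s, e) = base + noise_offset(s) + b_ecc * e
                  + (b_age + b_int * e) * (age - age_mean) + u_i

with subject random intercepts ``u_i ~ N(0, sigma_subject^2)``, ages drawn
from a truncated normal, and a floor keeping every cell threshold positive.
Default magnitudes are the calibration inputs of the study design: noise
offsets -1.761 / -1.228 / 0 deg relative to the high-noise reference,
eccentricity slope 0.056 deg/deg, age slope 0.031 deg/yr, subject-intercept
variance 0.145 deg^2, 42 subjects aged 21.1-44.1 (mean 32.35, SD 7.23).

Because simulation uses this additive map directly, a participant's "true"
internal noise and efficiency are defined as the closed-form
equivalent-noise decomposition of their true cell thresholds (see
``cohort_truth``); those derived traits are what recovery analyses are
checked against.  Trial-level stochasticity comes only from the Bernoulli
observer — there is no extra threshold jitter.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .equivnoise import fit_equivalent_noise
from .observer import SessionDesign, generate_session_design, run_session

__all__ = [
    "CohortSpec",
    "ParticipantProfile",
    "sample_cohort",
    "cohort_truth",
    "generate_study_dataset",
]


def _default_noise_offsets() -> dict[float, float]:
    return {0.5: -1.761, 1.5: -1.228, 3.0: 0.0}


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Population-level parameters of the synthetic cohort."""

    n_subjects: int = 42
    age_mean: float = 32.35
    age_sd: float = 7.23
    age_min: float = 21.1
    age_max: float = 44.1
    base_threshold_deg: float = 4.0
    noise_offsets: Mapping[float, float] = dataclasses.field(
        default_factory=_default_noise_offsets
    )
    ecc_slope: float = 0.056
    age_effect: float = 0.031
    age_ecc_interaction: float = 0.008
    subject_sd: float = float(np.sqrt(0.145))
    bias_sd_deg: float = 0.15
    lapse_rate: float = 0.02
    threshold_floor_deg: float = 0.2
    calibration_deg_per_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least 2 subjects")
        for name in ("age_sd", "subject_sd", "bias_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.age_min <= self.age_mean <= self.age_max:
            raise ValueError("age mean must lie within the stated range")
        min_expected = self.base_threshold_deg + min(self.noise_offsets.values())
        if min_expected <= 0:
            raise ValueError(
                "infeasible spec: expected threshold at the easiest noise level "
                f"is {min_expected:.3f} deg (base {self.base_threshold_deg} + "
                f"offset {min(self.noise_offsets.values())}); raise the base "
                "threshold or shrink the noise offsets"
            )


@dataclasses.dataclass
class ParticipantProfile:
    """One simulated participant: demographics plus realized trait map.

    ``level0_deg`` is the participant's expected threshold in the high-noise
    reference condition at 0 deg eccentricity (base + intercept + age main
    effect); ``ecc_coef`` the per-degree eccentricity slope including the
    participant's age x eccentricity term.  ``sigma_eff`` evaluates the
    additive map with the cohort floor applied, which is exactly the
    effective noise the Bernoulli observer uses on every trial.
    """

    subject_id: str
    age_years: float
    intercept_deg: float
    level0_deg: float
    ecc_coef: float
    noise_offsets: Mapping[float, float]
    bias_deg: float = 0.0
    lapse_rate: float = 0.02
    threshold_floor_deg: float = 0.2

    def __post_init__(self) -> None:
        keys = np.array(sorted(self.noise_offsets))
        vals = np.array([self.noise_offsets[k] for k in keys])
        self._keys = keys
        self._vals = vals

    def _noise_offset(self, noise_scale):
        s = np.asarray(noise_scale, dtype=float)
        idx = np.searchsorted(self._keys, s)
        if np.any(idx >= len(self._keys)) or np.any(self._keys[idx] != s):
            raise KeyError(f"unknown noise scale(s) in {np.unique(s)}")
        return self._vals[idx]

    def sigma_eff(self, noise_scale, eccentricity_deg):
        """Expected threshold sigma (deg) in the given condition(s)."""
        e = np.asarray(eccentricity_deg, dtype=float)
        sigma = self.level0_deg + self._noise_offset(noise_scale) + self.ecc_coef * e
        out = np.maximum(sigma, self.threshold_floor_deg)
        return float(out) if out.ndim == 0 else out


def sample_cohort(
    spec: CohortSpec, rng: np.random.Generator
) -> list[ParticipantProfile]:
    """Draw a cohort of participants from the population spec."""
    a = (spec.age_min - spec.age_mean) / spec.age_sd if spec.age_sd > 0 else -np.inf
    b = (spec.age_max - spec.age_mean) / spec.age_sd if spec.age_sd > 0 else np.inf
    if spec.age_sd > 0:
        ages = truncnorm.rvs(
            a, b, loc=spec.age_mean, scale=spec.age_sd,
            size=spec.n_subjects, random_state=rng,
        )
    else:
        ages = np.full(spec.n_subjects, spec.age_mean)
    intercepts = rng.normal(0.0, spec.subject_sd, size=spec.n_subjects)
    biases = rng.normal(0.0, spec.bias_sd_deg, size=spec.n_subjects)
    width = len(str(spec.n_subjects))
    profiles = []
    for i in range(spec.n_subjects):
        dage = ages[i] - spec.age_mean
        profiles.append(
            ParticipantProfile(
                subject_id=f"S{i + 1:0{width}d}",
                age_years=float(ages[i]),
                intercept_deg=float(intercepts[i]),
                level0_deg=float(
                    spec.base_threshold_deg + intercepts[i] + spec.age_effect * dage
                ),
                ecc_coef=float(spec.ecc_slope + spec.age_ecc_interaction * dage),
                noise_offsets=dict(spec.noise_offsets),
                bias_deg=float(biases[i]),
                lapse_rate=spec.lapse_rate,
                threshold_floor_deg=spec.threshold_floor_deg,
            )
        )
    return profiles


def cohort_truth(
    profiles: Sequence[ParticipantProfile],
    noise_levels: Sequence[float] = (0.5, 1.5, 3.0),
    eccentricities: Sequence[float] = (0.0, 5.0, 10.0),
    calibration: float = 1.0,
) -> pd.DataFrame:
    """Ground-truth sidecar: true cell thresholds and derived traits.

    One row per subject x noise x eccentricity with the generating threshold,
    plus (repeated within subject x eccentricity) the derived true internal
    noise and efficiency from the closed-form equivalent-noise decomposition
    of those thresholds.  Used for parameter-recovery testing.
    """
    rows = []
    for p in profiles:
        for e in eccentricities:
            sigmas = np.array([p.sigma_eff(s, e) for s in noise_levels])
            fit = fit_equivalent_noise(sigmas, np.asarray(noise_levels), calibration)
            for s, sig in zip(noise_levels, sigmas):
                rows.append(
                    {
                        "subject_id": p.subject_id,
                        "age_years": p.age_years,
                        "intercept_deg": p.intercept_deg,
                        "bias_deg": p.bias_deg,
                        "noise_scale": s,
                        "eccentricity_deg": e,
                        "threshold_true_deg": sig,
                        "sigma_int_true_deg": fit.internal_noise_deg,
                        "efficiency_true": fit.efficiency,
                    }
                )
    return pd.DataFrame(rows)


def generate_study_dataset(
    spec: CohortSpec,
    rng: np.random.Generator,
    design_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one full study: a session per subject plus the truth sidecar.

    Each subject gets an independently randomized session (design and
    responses drawn from per-subject child generators, so the dataset is
    deterministic under a fixed parent seed).  Returns ``(trials, truth)``.
    """
    design_kwargs = dict(design_kwargs or {})
    profiles = sample_cohort(spec, rng)
    child_rngs = rng.spawn(len(profiles))
    frames = []
    design: SessionDesign | None = None
    for p, child in zip(profiles, child_rngs):
        design = generate_session_design(rng=child, **design_kwargs)
        frames.append(run_session(p, design, child, subject_id=p.subject_id))
    trials = pd.concat(frames, ignore_index=True)
    assert design is not None
    truth = cohort_truth(
        profiles,
        noise_levels=design.noise_levels,
        eccentricities=design.eccentricities,
        calibration=spec.calibration_deg_per_scale,
    )
    return trials, truth
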