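"""Equivalent-noise 2AFC observer and session design.

The observer judges whether a briefly presented Gabor is tilted clockwise
(CW) or counter-clockwise (CCW) of vertical.  Its sensitivity is summarised
by an effective orientation noise ``sigma_eff`` that combines
stimulus-imposed external noise with observer-specific internal noise under
a linear-amplifier equivalent-noise model::

    sigma_eff^2 = ( (sigma_int * (1 + kappa * ecc))^2 + (c * s)^2 ) / E

where ``s`` is the external-noise scale factor, ``c`` converts image-noise
scale into orientation-equivalent degrees, ``kappa`` is the fractional
internal-noise growth per degree of eccentricity and ``E`` in (0, 1] is the
observer's calculation efficiency.  The probability of a clockwise response
at signed offset ``x`` is a lapse-contaminated cumulative Gaussian::

    P(CW) = (1 - lambda) * Phi((x - mu) / sigma_eff) + lambda / 2

A session interleaves every noise x eccentricity x offset cell in random
order, with a small practice block up front and suprathreshold (+-8 deg)
catch trials sprinkled through the run to monitor engagement.  Trials are
carried as a pandas DataFrame with one row per trial (the ``TRIAL_COLUMNS``
schema) — the tabular form every downstream stage consumes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "CW",
    "CCW",
    "TRIAL_COLUMNS",
    "ObserverParams",
    "SessionDesign",
    "effective_threshold",
    "p_clockwise",
    "simulate_response",
    "generate_session_design",
    "run_session",
]

CW = "CW"
CCW = "CCW"

#: Fixed column order of the trial-record table (the CSV interchange schema).
TRIAL_COLUMNS = [
    "subject_id",
    "age_years",
    "noise_scale",
    "eccentricity_deg",
    "offset_deg",
    "hemifield",
    "is_catch",
    "is_practice",
    "trial_index",
    "response",
    "correct",
]


@dataclasses.dataclass(frozen=True)
class ObserverParams:
    """Latent traits of a simulated observer.

    ``internal_noise_deg`` is the orientation-equivalent internal noise at
    the fovea; ``efficiency`` the fraction of stimulus information used;
    ``ecc_noise_slope`` the fractional internal-noise growth per degree of
    eccentricity; ``bias_deg`` a constant decision bias; ``lapse_rate`` the
    probability of a stimulus-independent guess.
    """

    internal_noise_deg: float = 1.0
    efficiency: float = 1.0
    ecc_noise_slope: float = 0.0
    bias_deg: float = 0.0
    lapse_rate: float = 0.02
    age_years: float | None = None
    calibration_deg_per_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.internal_noise_deg < 0:
            raise ValueError("internal noise must be non-negative")
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in (0, 1]")
        if self.ecc_noise_slope < 0:
            raise ValueError("eccentricity noise slope must be non-negative")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse rate must lie in [0, 1]")

    def sigma_eff(self, noise_scale, eccentricity_deg):
        """Effective orientation noise (deg) for given conditions."""
        return effective_threshold(self, noise_scale, eccentricity_deg)


def effective_threshold(
    obs: ObserverParams,
    noise_scale,
    eccentricity_deg,
    calibration_deg_per_scale: float | None = None,
):
    """Equivalent-noise effective threshold ``sigma_eff`` in degrees.

    Accepts scalar or array conditions.  ``calibration_deg_per_scale``
    overrides the observer's stored external-noise calibration constant.
    """
    if obs.efficiency <= 0:
        raise ValueError("efficiency must be positive")
    c = (
        obs.calibration_deg_per_scale
        if calibration_deg_per_scale is None
        else calibration_deg_per_scale
    )
    s = np.asarray(noise_scale, dtype=float)
    ecc = np.asarray(eccentricity_deg, dtype=float)
    internal = obs.internal_noise_deg * (1.0 + obs.ecc_noise_slope * ecc)
    var = (internal**2 + (c * s) ** 2) / obs.efficiency
    out = np.sqrt(var)
    return float(out) if out.ndim == 0 else out


def p_clockwise(offset_deg, sigma_eff, bias_deg=0.0, lapse_rate=0.0):
    """Probability of a clockwise response at a signed orientation offset."""
    sigma = np.asarray(sigma_eff, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma_eff must be positive")
    lam = np.asarray(lapse_rate, dtype=float)
    if np.any((lam < 0) | (lam > 1)):
        raise ValueError("lapse rate must lie in [0, 1]")
    z = (np.asarray(offset_deg, dtype=float) - np.asarray(bias_deg, dtype=float)) / sigma
    p = (1.0 - lam) * ndtr(z) + lam / 2.0
    return float(p) if np.ndim(p) == 0 else p


def simulate_response(
    obs,
    noise_scale: float,
    eccentricity_deg: float,
    offset_deg: float,
    rng: np.random.Generator,
    subject_id: str = "obs",
    is_catch: bool = False,
    is_practice: bool = False,
    trial_index: int = 0,
    hemifield: str = "C",
) -> dict:
    """Simulate one 2AFC trial and return a trial record (dict).

    ``correct`` is defined objectively: a CW response is correct iff the
    offset is positive.  A zero offset has no correct answer and is rejected.
    """
    if offset_deg == 0:
        raise ValueError("offset 0 has undefined correctness in a 2AFC design")
    sigma = obs.sigma_eff(noise_scale, eccentricity_deg)
    p = p_clockwise(offset_deg, sigma, obs.bias_deg, obs.lapse_rate)
    resp = CW if rng.random() < p else CCW
    return {
        "subject_id": subject_id,
        "age_years": getattr(obs, "age_years", None),
        "noise_scale": noise_scale,
        "eccentricity_deg": eccentricity_deg,
        "offset_deg": offset_deg,
        "hemifield": hemifield,
        "is_catch": is_catch,
        "is_practice": is_practice,
        "trial_index": trial_index,
        "response": resp,
        "correct": (resp == CW) == (offset_deg > 0),
    }


@dataclasses.dataclass
class SessionDesign:
    """One observer's full trial schedule plus the timing metadata.

    ``trials`` holds the realized, randomized order: practice block first,
    then main and catch trials interleaved.  Timing fields are metadata only
    (the simulation has no temporal dynamics).
    """

    noise_levels: tuple[float, ...]
    eccentricities: tuple[float, ...]
    offsets_deg: tuple[float, ...]
    reps_per_cell: int
    catch_fraction: float
    practice_fraction: float
    trials: pd.DataFrame
    catch_offset_deg: float = 8.0
    fixation_ms: int = 500
    stimulus_ms: int = 100
    iti_range_ms: tuple[int, int] = (400, 800)
    hemifield_balanced: bool = True

    @property
    def n_main(self) -> int:
        return int((~self.trials.is_catch & ~self.trials.is_practice).sum())

    @property
    def n_catch(self) -> int:
        return int(self.trials.is_catch.sum())

    @property
    def n_practice(self) -> int:
        return int(self.trials.is_practice.sum())


DEFAULT_OFFSETS = (-8.0, -6.0, -4.0, -2.0, -1.0, 1.0, 2.0, 4.0, 6.0, 8.0)


def generate_session_design(
    noise_levels: Sequence[float] = (0.5, 1.5, 3.0),
    eccentricities: Sequence[float] = (0.0, 5.0, 10.0),
    offsets_deg: Sequence[float] = DEFAULT_OFFSETS,
    reps_per_cell: int = 8,
    catch_fraction: float = 0.08,
    practice_fraction: float = 0.05,
    catch_offset_deg: float = 8.0,
    rng: np.random.Generator | None = None,
) -> SessionDesign:
    """Build one randomized session.

    Every noise x eccentricity x offset cell appears exactly
    ``reps_per_cell`` times; catch trials (suprathreshold +-8 deg offsets,
    flagged) make up ``catch_fraction`` of the main trial count and practice
    trials ``practice_fraction``, the latter forming an initial block that
    analyses exclude by default.  Hemifields are balanced within each
    peripheral cell (centre presentations carry hemifield 'C').
    """
    offsets = tuple(float(o) for o in offsets_deg)
    if len(offsets) == 0:
        raise ValueError("offset set must not be empty")
    if any(o == 0 for o in offsets):
        raise ValueError("offsets must be nonzero")
    if set(offsets) != {-o for o in offsets}:
        raise ValueError("offset set must be symmetric about 0")
    if not (0 <= catch_fraction < 1 and 0 <= practice_fraction < 1):
        raise ValueError("catch/practice fractions must lie in [0, 1)")
    if reps_per_cell < 1:
        raise ValueError("reps_per_cell must be at least 1")
    if rng is None:
        rng = np.random.default_rng()

    cells = [
        (s, e, o) for s in noise_levels for e in eccentricities for o in offsets
    ]
    rows: list[tuple] = []
    for s, e, o in cells:
        for r in range(reps_per_cell):
            if e == 0:
                hemi = "C"
            else:
                hemi = "L" if r % 2 == 0 else "R"
            rows.append((s, e, o, hemi, False, False))
    n_main = len(rows)

    n_catch = int(round(catch_fraction * n_main))
    conds = [(s, e) for s in noise_levels for e in eccentricities]
    for i in range(n_catch):
        s, e = conds[int(rng.integers(len(conds)))]
        o = catch_offset_deg if i % 2 == 0 else -catch_offset_deg
        hemi = "C" if e == 0 else ("L" if rng.random() < 0.5 else "R")
        rows.append((s, e, o, hemi, True, False))

    main_and_catch = pd.DataFrame(
        rows,
        columns=[
            "noise_scale",
            "eccentricity_deg",
            "offset_deg",
            "hemifield",
            "is_catch",
            "is_practice",
        ],
    )
    order = rng.permutation(len(main_and_catch))
    main_and_catch = main_and_catch.iloc[order].reset_index(drop=True)

    n_practice = int(round(practice_fraction * n_main))
    practice_idx = rng.integers(0, n_main, size=n_practice)
    practice = pd.DataFrame(
        [rows[i] for i in practice_idx], columns=main_and_catch.columns
    )
    practice["is_practice"] = True
    practice["is_catch"] = False

    if len(practice):
        trials = pd.concat([practice, main_and_catch], ignore_index=True)
    else:
        trials = main_and_catch
    trials.insert(0, "trial_index", np.arange(len(trials)))
    return SessionDesign(
        noise_levels=tuple(noise_levels),
        eccentricities=tuple(eccentricities),
        offsets_deg=offsets,
        reps_per_cell=reps_per_cell,
        catch_fraction=catch_fraction,
        practice_fraction=practice_fraction,
        catch_offset_deg=catch_offset_deg,
        trials=trials,
    )


def run_session(
    obs,
    design: SessionDesign,
    rng: np.random.Generator,
    subject_id: str = "obs",
) -> pd.DataFrame:
    """Simulate an observer through a session; one row per trial.

    ``obs`` may be any object with ``sigma_eff(noise_scale, ecc)`` plus
    ``bias_deg`` and ``lapse_rate`` attributes (an :class:`ObserverParams`
    or a cohort ``ParticipantProfile``).  Draws are vectorized over the
    whole session, so a fixed generator state yields an identical record
    stream.
    """
    t = design.trials
    sigma = np.asarray(
        obs.sigma_eff(t.noise_scale.to_numpy(), t.eccentricity_deg.to_numpy()),
        dtype=float,
    )
    p = p_clockwise(
        t.offset_deg.to_numpy(), sigma, obs.bias_deg, obs.lapse_rate
    )
    cw = rng.random(len(t)) < p
    out = t.copy()
    out.insert(0, "subject_id", subject_id)
    out.insert(1, "age_years", getattr(obs, "age_years", np.nan))
    out["response"] = np.where(cw, CW, CCW)
    out["correct"] = cw == (t.offset_deg.to_numpy() > 0)
    return out[TRIAL_COLUMNS]
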