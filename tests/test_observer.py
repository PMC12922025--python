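"""Equivalent-noise observer and session design."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from oridisc.observer import (
    TRIAL_COLUMNS,
    ObserverParams,
    effective_threshold,
    generate_session_design,
    p_clockwise,
    run_session,
    simulate_response,
)


class TestEffectiveThreshold:
    def test_external_noise_limited_regime(self):
        obs = ObserverParams(internal_noise_deg=0.0, efficiency=1.0)
        for s in (0.5, 1.5, 3.0):
            assert effective_threshold(obs, s, 0.0) == pytest.approx(s)

    def test_internal_noise_limited_regime(self):
        obs = ObserverParams(internal_noise_deg=1.2, efficiency=0.36,
                             ecc_noise_slope=0.1)
        expected = 1.2 * (1 + 0.1 * 5.0) / math.sqrt(0.36)
        assert effective_threshold(obs, 0.0, 5.0) == pytest.approx(expected)

    def test_spec_algebra_example(self):
        obs = ObserverParams(internal_noise_deg=1.0, efficiency=0.5)
        var = [effective_threshold(obs, s, 0.0) ** 2 for s in (0.5, 1.5, 3.0)]
        np.testing.assert_allclose(var, [2.5, 6.5, 20.0], rtol=1e-12)

    def test_monotone_in_noise_eccentricity_and_inefficiency(self):
        kw = dict(internal_noise_deg=1.0, ecc_noise_slope=0.05)
        obs = ObserverParams(efficiency=0.8, **kw)
        assert (effective_threshold(obs, 3.0, 0) > effective_threshold(obs, 1.5, 0)
                > effective_threshold(obs, 0.5, 0))
        assert (effective_threshold(obs, 1.5, 10) > effective_threshold(obs, 1.5, 5)
                > effective_threshold(obs, 1.5, 0))
        worse = ObserverParams(efficiency=0.4, **kw)
        assert effective_threshold(worse, 1.5, 5) > effective_threshold(obs, 1.5, 5)

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(efficiency=0.0)
        with pytest.raises(ValueError):
            ObserverParams(efficiency=1.5)


class TestPClockwise:
    def test_half_at_bias_point_for_any_lapse(self):
        for lam in (0.0, 0.05, 0.5, 1.0):
            assert p_clockwise(1.3, 2.0, bias_deg=1.3, lapse_rate=lam) == 0.5

    def test_one_sigma_closed_form(self):
        assert p_clockwise(2.5, 2.5) == pytest.approx(ndtr(1.0), abs=1e-12)

    def test_full_lapse_is_pure_guessing(self):
        offsets = np.array([-8.0, -1.0, 1.0, 8.0])
        np.testing.assert_allclose(p_clockwise(offsets, 1.0, lapse_rate=1.0), 0.5)

    def test_equal_offset_symmetry_without_bias(self):
        # P(correct | +theta) == P(correct | -theta) when mu = 0
        p_cw = p_clockwise(3.0, 2.0, lapse_rate=0.04)
        p_ccw = 1.0 - p_clockwise(-3.0, 2.0, lapse_rate=0.04)
        assert p_cw == pytest.approx(p_ccw, abs=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            p_clockwise(1.0, 0.0)


class TestSimulateResponse:
    def test_zero_offset_rejected(self, rng):
        obs = ObserverParams()
        with pytest.raises(ValueError):
            simulate_response(obs, 1.5, 0.0, 0.0, rng)

    def test_empirical_rate_matches_model(self, rng):
        obs = ObserverParams(internal_noise_deg=2.0, efficiency=0.8,
                             lapse_rate=0.03)
        p = p_clockwise(1.0, obs.sigma_eff(1.5, 5.0), 0.0, 0.03)
        n = 10_000
        hits = sum(
            simulate_response(obs, 1.5, 5.0, 1.0, rng, trial_index=i)["response"]
            == "CW"
            for i in range(n)
        )
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_suprathreshold_accuracy_near_one(self, rng):
        obs = ObserverParams(internal_noise_deg=1.0, efficiency=1.0,
                             lapse_rate=0.0)
        recs = [simulate_response(obs, 0.0, 0.0, 8.0, rng, trial_index=i)
                for i in range(500)]
        assert np.mean([r["correct"] for r in recs]) == 1.0

    def test_same_seed_same_stream(self):
        obs = ObserverParams()
        a = [simulate_response(obs, 1.5, 5.0, 2.0, np.random.default_rng(9),
                               trial_index=i) for i in range(20)]
        b = [simulate_response(obs, 1.5, 5.0, 2.0, np.random.default_rng(9),
                               trial_index=i) for i in range(20)]
        assert a == b


class TestSessionDesign:
    def test_default_trial_counts(self, rng):
        d = generate_session_design(rng=rng)
        assert d.n_main == 720
        assert d.n_catch == 58
        assert d.n_practice == 36

    def test_cells_exactly_balanced(self, rng):
        d = generate_session_design(rng=rng)
        main = d.trials[~d.trials.is_catch & ~d.trials.is_practice]
        counts = main.groupby(
            ["noise_scale", "eccentricity_deg", "offset_deg"]
        ).size()
        assert len(counts) == 90
        assert (counts == 8).all()

    def test_no_catch_when_fraction_zero(self, rng):
        d = generate_session_design(catch_fraction=0.0, rng=rng)
        assert d.n_catch == 0

    def test_hemifields_balanced_in_periphery(self, rng):
        d = generate_session_design(rng=rng)
        main = d.trials[~d.trials.is_catch & ~d.trials.is_practice]
        periph = main[main.eccentricity_deg > 0]
        by_cell = periph.groupby(
            ["noise_scale", "eccentricity_deg", "offset_deg"]
        ).hemifield.apply(lambda h: (h == "L").sum() == (h == "R").sum())
        assert by_cell.all()
        assert (main[main.eccentricity_deg == 0].hemifield == "C").all()

    def test_bad_offset_sets_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_session_design(offsets_deg=(), rng=rng)
        with pytest.raises(ValueError):
            generate_session_design(offsets_deg=(1.0, 2.0), rng=rng)
        with pytest.raises(ValueError):
            generate_session_design(offsets_deg=(-1.0, 0.0, 1.0), rng=rng)


class TestRunSession:
    def test_record_schema_and_determinism(self):
        obs = ObserverParams(age_years=30.0)
        d = generate_session_design(rng=np.random.default_rng(5))
        a = run_session(obs, d, np.random.default_rng(6), subject_id="S1")
        b = run_session(obs, d, np.random.default_rng(6), subject_id="S1")
        assert list(a.columns) == TRIAL_COLUMNS
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_sigma_gives_perfect_accuracy(self):
        obs = ObserverParams(internal_noise_deg=0.01, efficiency=1.0,
                             lapse_rate=0.0)
        d = generate_session_design(
            noise_levels=(0.01,), eccentricities=(0.0,), reps_per_cell=2,
            rng=np.random.default_rng(2),
        )
        rec = run_session(obs, d, np.random.default_rng(3))
        assert rec.correct.all()

    def test_sensitive_observer_keeps_catch_accuracy_high(self):
        # sigma_eff <= 2 deg everywhere -> near-ceiling on +-8 deg catches
        obs = ObserverParams(internal_noise_deg=1.0, efficiency=0.6,
                             ecc_noise_slope=0.02)
        assert obs.sigma_eff(3.0, 10.0) > obs.sigma_eff(0.5, 0.0)
        d = generate_session_design(noise_levels=(0.25, 0.5, 1.0),
                                    rng=np.random.default_rng(21))
        rec = run_session(obs, d, np.random.default_rng(22))
        catch_acc = rec[rec.is_catch].correct.mean()
        assert catch_acc >= 0.96

    def test_accuracy_monotone_in_noise_and_offset(self):
        # checked in expectation over >= 10^4 trials per noise level
        obs = ObserverParams(internal_noise_deg=1.5, efficiency=0.7,
                             ecc_noise_slope=0.03)
        d = generate_session_design(reps_per_cell=40, catch_fraction=0.0,
                                    practice_fraction=0.0,
                                    rng=np.random.default_rng(31))
        rec = run_session(obs, d, np.random.default_rng(32))
        acc_noise = rec.groupby("noise_scale").correct.mean()
        assert acc_noise.loc[0.5] > acc_noise.loc[1.5] > acc_noise.loc[3.0]
        acc_ecc = rec.groupby("eccentricity_deg").correct.mean()
        assert acc_ecc.loc[0.0] > acc_ecc.loc[10.0]
        acc_off = rec.assign(a=rec.offset_deg.abs()).groupby("a").correct.mean()
        assert acc_off.is_monotonic_increasing
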