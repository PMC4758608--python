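"""Phase extraction and PSI: identities, brute force, filters, statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thetawhisk.data_model import ContinuousSignal, EpisodeWindow
from thetawhisk.phase_sync import (
    PSI_WINDOW_S,
    THETA_BAND,
    PhaseSeries,
    align_phase_to,
    bandpass_theta,
    compute_psi,
    instantaneous_phase,
    pairwise_psi_matrix,
    phase_delay_stats,
    psi_behavior_tests,
    psi_bias_correct,
    psi_chance_level,
    trial_metrics,
    two_sample_randomization_test,
)

FS = 2000.0


def _series(phases, fs=FS, t0=0.0):
    return PhaseSeries(np.asarray(phases, float), fs, t0)


def _win(n, fs=FS, t0=0.0, label="touch"):
    return EpisodeWindow(label, t0, t0 + n / fs)


# ---------------------------------------------------------------------------
# PSI identities and brute force
# ---------------------------------------------------------------------------


class TestPSIIdentities:
    def test_constant_difference_gives_one(self, rng):
        phx = rng.uniform(-np.pi, np.pi, 500)
        phy = phx - 0.8
        res = compute_psi(_series(phx), _series(phy), _win(500))
        assert np.isclose(res.psi, 1.0, atol=1e-12)
        assert np.isclose(res.mean_delay_rad, 0.8, atol=1e-12)

    def test_four_symmetric_differences_give_zero(self):
        phx = np.array([0.0, np.pi / 2, np.pi, -np.pi / 2])
        phy = np.zeros(4)
        res = compute_psi(_series(phx), _series(phy), _win(4))
        assert np.isclose(res.psi, 0.0, atol=1e-12)

    def test_brute_force_small_samples(self, rng):
        for n in (2, 5, 11, 20):
            phx = rng.uniform(-np.pi, np.pi, n)
            phy = rng.uniform(-np.pi, np.pi, n)
            d = phx - phy
            expected = np.hypot(np.cos(d).mean(), np.sin(d).mean())
            res = compute_psi(_series(phx), _series(phy), _win(n))
            assert np.isclose(res.psi, expected, rtol=0, atol=1e-12)

    def test_nm_ratio_locking(self, rng):
        # φx advancing twice as fast as φy is perfectly 1:2 locked
        base = np.cumsum(rng.uniform(0.01, 0.05, 400))
        phx, phy = 2 * base, base
        res12 = compute_psi(_series(phx), _series(phy), _win(400), n=1, m=2)
        assert np.isclose(res12.psi, 1.0, atol=1e-12)

    @given(st.floats(-np.pi, np.pi))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_common_rotation(self, shift):
        rng = np.random.default_rng(5)
        phx = rng.uniform(-np.pi, np.pi, 100)
        phy = rng.uniform(-np.pi, np.pi, 100)
        a = compute_psi(_series(phx), _series(phy), _win(100)).psi
        b = compute_psi(_series(phx + shift), _series(phy + shift), _win(100)).psi
        assert np.isclose(a, b, atol=1e-9)

    def test_psi_bounded(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50))
            res = compute_psi(
                _series(rng.uniform(-np.pi, np.pi, n)),
                _series(rng.uniform(-np.pi, np.pi, n)),
                _win(n),
            )
            assert 0.0 <= res.psi <= 1.0 + 1e-12

    def test_window_too_small(self, rng):
        with pytest.raises(ValueError):
            compute_psi(_series([0.1] * 10), _series([0.2] * 10), _win(1))


# ---------------------------------------------------------------------------
# Band-pass and Hilbert phase
# ---------------------------------------------------------------------------


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(int(10 * FS)) / FS
        x = ContinuousSignal(np.cos(2 * np.pi * 8.0 * t), FS)
        y = bandpass_theta(x)
        core = slice(int(FS), int(9 * FS))
        assert np.std(y.samples[core]) / np.std(x.samples[core]) > 0.99

    def test_out_of_band_tones_rejected(self):
        t = np.arange(int(10 * FS)) / FS
        for f in (1.0, 40.0):
            x = ContinuousSignal(np.cos(2 * np.pi * f * t), FS)
            y = bandpass_theta(x)
            core = slice(int(FS), int(9 * FS))
            assert np.std(y.samples[core]) < 0.05

    def test_zero_phase_preserves_peaks(self):
        t = np.arange(int(10 * FS)) / FS
        x = ContinuousSignal(np.cos(2 * np.pi * 8.0 * t), FS)
        y = bandpass_theta(x)
        core = slice(int(FS), int(9 * FS))
        # zero-phase filtering: in-band tone passes with no shift
        assert np.corrcoef(x.samples[core], y.samples[core])[0, 1] > 0.9999

    def test_rejects_low_sample_rate(self):
        with pytest.raises(ValueError):
            bandpass_theta(ContinuousSignal(np.ones(100), 20.0))

    def test_rejects_short_signal(self):
        with pytest.raises(ValueError):
            bandpass_theta(ContinuousSignal(np.zeros(100), FS))


class TestInstantaneousPhase:
    def test_cosine_phase_ramp(self):
        f0 = 8.0
        t = np.arange(int(10 * FS)) / FS
        sig = ContinuousSignal(np.cos(2 * np.pi * f0 * t), FS)
        ph = instantaneous_phase(bandpass_theta(sig))
        core = slice(int(FS), int(9 * FS))
        unwrapped = np.unwrap(ph.phases)[core]
        slope = np.polyfit(t[core], unwrapped, 1)[0]
        assert np.isclose(slope / (2 * np.pi), f0, atol=0.01)
        # cosine convention: phase 0 at maxima
        peaks = np.isclose(np.cos(2 * np.pi * f0 * t[core]), 1.0, atol=1e-6)
        assert np.all(np.abs(ph.phases[core][peaks]) < 0.05)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(ContinuousSignal(np.ones(1000), FS))

    def test_frequency_recovered_for_any_in_band_tone(self, rng):
        f0 = float(rng.uniform(5.5, 11.5))
        t = np.arange(int(8 * FS)) / FS
        sig = ContinuousSignal(np.cos(2 * np.pi * f0 * t + 1.0), FS)
        ph = instantaneous_phase(bandpass_theta(sig))
        core = slice(int(FS), int(7 * FS))
        slope = np.polyfit(t[core], np.unwrap(ph.phases)[core], 1)[0]
        assert np.isclose(slope / (2 * np.pi), f0, atol=0.02)


class TestAlignPhase:
    def test_identity_alignment(self, rng):
        ph = np.unwrap(rng.uniform(-0.1, 0.4, 4000).cumsum() % (2 * np.pi))
        from thetawhisk.spike_phase import wrap_phase

        x = _series(wrap_phase(ph))
        w = EpisodeWindow("touch", 0.5, 1.0)
        aligned = align_phase_to(x, x, w)
        assert np.allclose(aligned, x.window_slice(w), atol=1e-9)

    def test_downsampled_alignment(self):
        # whisking at half rate: aligned phase interpolates correctly
        f0 = 8.0
        n = 8000
        t_hi = np.arange(n) / FS
        t_lo = np.arange(n // 2) / (FS / 2)
        from thetawhisk.spike_phase import wrap_phase

        hi = _series(wrap_phase(2 * np.pi * f0 * t_hi), FS)
        lo = _series(wrap_phase(2 * np.pi * f0 * t_lo), FS / 2)
        w = EpisodeWindow("touch", 1.0, 2.0)
        aligned = align_phase_to(lo, hi, w)
        assert np.allclose(
            np.exp(1j * aligned), np.exp(1j * hi.window_slice(w)), atol=1e-3
        )

    def test_window_outside_coverage(self):
        x = _series(np.zeros(100) + 0.1)
        with pytest.raises(ValueError):
            align_phase_to(x, x, EpisodeWindow("touch", 5.0, 6.0))


class TestBiasCorrect:
    def test_skewed_phases_are_uniformized(self, rng):
        phases = rng.vonmises(0.5, 1.0, 20000)
        out = psi_bias_correct(_series(phases))
        assert out.bias_corrected
        from thetawhisk.spike_phase import rayleigh_test

        _, p = rayleigh_test(out.phases)
        assert p > 0.99  # rank remap gives a uniform marginal by construction

    def test_uniform_phases_left_alone(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 20000)
        out = psi_bias_correct(_series(phases))
        assert not out.bias_corrected
        assert np.array_equal(out.phases, phases)

    def test_small_sample_passthrough(self, rng):
        phases = rng.vonmises(0.0, 2.0, 50)
        out = psi_bias_correct(_series(phases))
        assert not out.bias_corrected

    def test_remap_is_monotone_in_phase_order(self, rng):
        phases = rng.vonmises(0.0, 1.5, 5000)
        out = psi_bias_correct(_series(phases))
        order = np.argsort(phases)
        assert np.all(np.diff(out.phases[order]) >= 0)


# ---------------------------------------------------------------------------
# Shuffle null
# ---------------------------------------------------------------------------


class TestChanceLevel:
    def _pairs(self, rng, n_trials=20, n_samp=500, locked=True):
        pairs = []
        for _ in range(n_trials):
            phx = np.cumsum(rng.normal(0.025, 0.01, n_samp))
            if locked:
                phy = phx - 1.0 + rng.normal(0, 0.05, n_samp)
            else:
                phy = np.cumsum(rng.normal(0.025, 0.01, n_samp)) + rng.uniform(
                    0, 2 * np.pi
                )
            pairs.append((phx, phy))
        return pairs

    def test_pairwise_matrix_matches_loop(self, rng):
        pairs = self._pairs(rng, n_trials=6, n_samp=40)
        theta = np.stack([p[0] for p in pairs])
        whisk = np.stack([p[1] for p in pairs])
        M = pairwise_psi_matrix(theta, whisk)
        for i in range(6):
            for j in range(6):
                d = theta[i] - whisk[j]
                assert np.isclose(
                    M[i, j], np.hypot(np.cos(d).mean(), np.sin(d).mean()), atol=1e-12
                )

    def test_locked_pairs_exceed_chance(self, rng):
        pairs = self._pairs(rng, locked=True)
        theta = np.stack([p[0] for p in pairs])
        whisk = np.stack([p[1] for p in pairs])
        observed = np.diag(pairwise_psi_matrix(theta, whisk)).mean()
        null = psi_chance_level(pairs, n_shuffles=200, seed=0)
        assert observed > null.chance_level

    def test_deterministic_given_seed(self, rng):
        pairs = self._pairs(rng)
        a = psi_chance_level(pairs, n_shuffles=100, seed=3)
        b = psi_chance_level(pairs, n_shuffles=100, seed=3)
        assert np.array_equal(a.shuffled_psi, b.shuffled_psi)
        assert a.chance_level == b.chance_level

    def test_percentile_definition(self, rng):
        pairs = self._pairs(rng)
        null = psi_chance_level(pairs, n_shuffles=150, seed=1)
        assert np.isclose(null.chance_level, np.percentile(null.shuffled_psi, 97.5))

    def test_normal_method(self, rng):
        pairs = self._pairs(rng)
        null = psi_chance_level(pairs, n_shuffles=150, seed=1, method="normal")
        m, s = null.shuffled_psi.mean(), null.shuffled_psi.std(ddof=1)
        assert np.isclose(null.chance_level, m + 1.96 * s)

    def test_requires_ten_trials(self, rng):
        with pytest.raises(ValueError):
            psi_chance_level(self._pairs(rng, n_trials=5), n_shuffles=10, seed=0)

    def test_mismatched_lengths_rejected(self, rng):
        pairs = self._pairs(rng)
        pairs[0] = (pairs[0][0][:-1], pairs[0][1][:-1])
        with pytest.raises(ValueError):
            psi_chance_level(pairs, n_shuffles=10, seed=0)


# ---------------------------------------------------------------------------
# Delay statistics, randomization test, trial metrics
# ---------------------------------------------------------------------------


class TestDelayStats:
    def test_clustered_delays(self, rng):
        from thetawhisk.phase_sync import PSIResult

        res = [
            PSIResult(psi=0.9, mean_delay_rad=1.6 + rng.normal(0, 0.1), n_samples=100)
            for _ in range(40)
        ]
        mean, p = phase_delay_stats(res)
        assert abs(mean - 1.6) < 0.1
        assert p < 1e-6

    def test_threshold_filters_trials(self, rng):
        from thetawhisk.phase_sync import PSIResult

        res = [
            PSIResult(psi=0.2, mean_delay_rad=float(d), n_samples=100)
            for d in rng.uniform(-np.pi, np.pi, 30)
        ] + [
            PSIResult(psi=0.9, mean_delay_rad=1.6, n_samples=100) for _ in range(10)
        ]
        mean, p = phase_delay_stats(res, psi_threshold=0.5)
        assert np.isclose(mean, 1.6)
        with pytest.raises(ValueError):
            phase_delay_stats(res[:30], psi_threshold=0.5)


class TestRandomizationTest:
    def test_detects_large_shift(self, rng):
        a = rng.normal(1.0, 0.1, 50)
        b = rng.normal(0.0, 0.1, 50)
        diff, p = two_sample_randomization_test(a, b, n_iter=999, seed=0)
        assert np.isclose(diff, a.mean() - b.mean())
        assert p == 1.0 / 1000

    def test_null_p_not_small(self, rng):
        a = rng.normal(0.0, 1.0, 60)
        b = rng.normal(0.0, 1.0, 60)
        _, p = two_sample_randomization_test(a, b, n_iter=500, seed=1)
        assert p > 0.01

    def test_add_one_rule_floor(self, rng):
        a = rng.normal(10.0, 0.01, 20)
        b = rng.normal(0.0, 0.01, 20)
        _, p = two_sample_randomization_test(a, b, n_iter=99, seed=2)
        assert p >= 1.0 / 100

    def test_deterministic(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.2, 1, 30)
        r1 = two_sample_randomization_test(a, b, n_iter=200, seed=9)
        r2 = two_sample_randomization_test(a, b, n_iter=200, seed=9)
        assert r1 == r2


def _metrics_frame(rng, n=60):
    psi_a = rng.uniform(0.3, 0.9, n)
    psi_t = np.clip(psi_a + rng.normal(0.1, 0.1, n), 0, 1)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "psi_approach": psi_a,
            "psi_touch": psi_t,
            "touch_duration_s": rng.uniform(0.1, 2.1, n),
            "correct": rng.random(n) < 0.75,
        }
    )


class TestTrialMetrics:
    def test_exclusion_flags(self, rng):
        df = _metrics_frame(rng)
        out = trial_metrics(df)
        lo, hi = 0.15, 2.0
        expected = (df["touch_duration_s"] < lo) | (df["touch_duration_s"] > hi)
        assert np.array_equal(out["excluded"].to_numpy(), expected.to_numpy())

    def test_normalized_duration_uses_max_over_kept_trials(self, rng):
        df = _metrics_frame(rng)
        out = trial_metrics(df)
        kept = out.loc[~out["excluded"]]
        dmax = kept["touch_duration_s"].max()
        assert np.allclose(
            out["normalized_duration"], dmax - out["touch_duration_s"]
        )

    def test_psi_change_definition(self, rng):
        out = trial_metrics(_metrics_frame(rng))
        assert np.allclose(out["psi_change"], out["psi_touch"] - out["psi_approach"])

    def test_group_boundaries(self, rng):
        out = trial_metrics(_metrics_frame(rng))
        kept = out.loc[~out["excluded"]]
        m, s = kept["touch_duration_s"].mean(), kept["touch_duration_s"].std(ddof=1)
        fast = out.loc[out["duration_group"] == "fast", "touch_duration_s"]
        slow = out.loc[out["duration_group"] == "slow", "touch_duration_s"]
        assert (fast < m - 0.4 * s).all()
        assert (slow > m + 0.4 * s).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            trial_metrics(pd.DataFrame({"trial_id": [0], "psi_touch": [0.5]}))

    def test_per_rat_normalization(self, rng):
        df = _metrics_frame(rng, n=40)
        df["rat"] = np.repeat(["a", "b"], 20)
        out = trial_metrics(df, rat_col="rat")
        for _, g in out.groupby("rat"):
            kept = g.loc[~g["excluded"]]
            assert np.isclose(
                kept["normalized_duration"].min(), 0.0
            )  # per-rat max maps to 0


class TestBehaviorTests:
    def test_report_structure_and_planted_direction(self, rng):
        n = 200
        psi_a = rng.uniform(0.4, 0.8, n)
        psi_t = np.clip(psi_a + rng.normal(0.15, 0.08, n), 0, 1)
        change = psi_t - psi_a
        z = (change - change.mean()) / change.std()
        dur = np.clip(0.54 - 0.2 * (0.6 * z + 0.8 * rng.standard_normal(n)), 0.16, 1.9)
        df = pd.DataFrame(
            {
                "trial_id": np.arange(n),
                "psi_approach": psi_a,
                "psi_touch": psi_t,
                "touch_duration_s": dur,
                "correct": rng.random(n) < 0.75,
            }
        )
        rep = psi_behavior_tests(trial_metrics(df), n_randomization=500, seed=0)
        assert rep["n_trials"] == int((~trial_metrics(df)["excluded"]).sum())
        overall = rep["correlation_overall"]
        assert overall["r"] > 0.3 and overall["p"] < 1e-4
        assert "wilcoxon_by_duration_group" in rep
        assert "psi_touch_correct_vs_incorrect" in rep

    def test_requires_enough_trials(self, rng):
        df = trial_metrics(_metrics_frame(rng, n=60)).iloc[:5]
        with pytest.raises(ValueError):
            psi_behavior_tests(df, seed=0)
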