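"""End-to-end orchestration: simulate → segment → spectra → PSI → spikes → report.

Every stage consumes explicit seeds derived from the session seed, so an
identical config yields an identical report.  The report gathers per-episode
spectral summaries, per-trial PSI metrics with their shuffle chance level,
the PSI-versus-behavior statistics, and per-condition spike phase-locking
summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    EpisodeWindow,
    SessionBundle,
    extract_window,
    segment_episodes,
    waiting_windows,
)
from .phase_sync import (
    PSI_WINDOW_S,
    PhaseSeries,
    PSIResult,
    bandpass_theta,
    compute_psi,
    instantaneous_phase,
    phase_delay_stats,
    psi_bias_correct,
    psi_chance_level,
    psi_behavior_tests,
    trial_metrics,
)
from .spectral import (
    episode_spectrum,
    normalize_power,
    peak_theta_frequency,
    power_randomization_test,
)
from .spike_phase import (
    assign_spike_phases,
    fit_von_mises,
    population_phase_summary,
    two_proportion_ztest,
)
from .synthetic import SimConfig, gen_coupled_pair, gen_session


@dataclass
class AnalysisReport:
    """Bundle of every pipeline output plus provenance."""

    provenance: dict
    spectral: dict
    psi: dict
    metrics: pd.DataFrame
    behavior: dict
    spikes: dict

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "spectral": self.spectral,
            "psi": self.psi,
            "behavior": self.behavior,
            "spikes": self.spikes,
        }
        return json.dumps(payload, indent=2, default=_json_default, sort_keys=True)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.metrics.to_csv(out / "trial_metrics.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config: SimConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Phase extraction
# ---------------------------------------------------------------------------

def session_phases(bundle: SessionBundle, bias_correct: bool = True):
    """Band-pass both signals, extract Hilbert phases, apply the rank-based
    bias correction when the session-wide phase distribution is non-uniform."""
    theta = instantaneous_phase(bandpass_theta(bundle.lfp))
    whisk = instantaneous_phase(bandpass_theta(bundle.whisking))
    if bias_correct:
        theta = psi_bias_correct(theta)
        whisk = psi_bias_correct(whisk)
    return theta, whisk


def per_trial_psi(
    bundle: SessionBundle,
    theta_phase: PhaseSeries,
    whisk_phase: PhaseSeries,
    window_s: float = PSI_WINDOW_S,
) -> pd.DataFrame:
    """Per-trial PSI for the approach window (ending at contact onset) and the
    touch window (starting at contact onset).

    Both windows have the same fixed length ``window_s`` on every trial:
    equal-length windows across trials are required for the across-trial
    shuffle comparison, and keep the estimator's finite-sample bias identical
    for all trials.  For touches shorter than ``window_s`` the touch window
    extends past contact offset into the immediate post-contact interval.
    """
    rows = []
    for ev in bundle.events:
        L = window_s
        wa = EpisodeWindow("approach", ev.contact_onset_s - L, ev.contact_onset_s, ev.trial_id)
        wt = EpisodeWindow("touch", ev.contact_onset_s, ev.contact_onset_s + L, ev.trial_id)
        ra = compute_psi(theta_phase, whisk_phase, wa)
        rt = compute_psi(theta_phase, whisk_phase, wt)
        rows.append(
            {
                "trial_id": ev.trial_id,
                "psi_approach": ra.psi,
                "psi_touch": rt.psi,
                "delay_approach": ra.mean_delay_rad,
                "delay_touch": rt.mean_delay_rad,
                "touch_duration_s": ev.touch_duration_s,
                "correct": ev.correct,
            }
        )
    return pd.DataFrame(rows)


def psi_trial_windows(
    bundle: SessionBundle,
    theta_phase: PhaseSeries,
    whisk_phase: PhaseSeries,
    episode: str = "touch",
    window_s: float = PSI_WINDOW_S,
):
    """Equal-length (theta, whisking) phase-window pairs for the shuffle null.

    Windows have the same fixed length ``window_s`` on every trial, matching
    :func:`per_trial_psi`.  Whisking phase is aligned to the theta sample grid.
    """
    from .phase_sync import align_phase_to

    pairs = []
    for ev in bundle.events:
        onset = ev.contact_onset_s
        if episode == "touch":
            w = EpisodeWindow("touch", onset, onset + window_s, ev.trial_id)
        elif episode == "approach":
            w = EpisodeWindow("approach", onset - window_s, onset, ev.trial_id)
        else:
            raise ValueError(f"unknown episode {episode!r}")
        px = theta_phase.window_slice(w)
        py = align_phase_to(whisk_phase, theta_phase, w)
        pairs.append((px, py))
    return pairs


def simulate_psi_windows(
    config: SimConfig,
    n_trials: int,
    window_s: float = PSI_WINDOW_S,
    seed=None,
    pad_s: float = 0.625,
):
    """Independent analysis-grade phase-window pairs from the full signal path.

    Each trial is its own short coupled-pair simulation (band-passed, Hilbert
    transformed); returns stacked (n_trials, n_samples) theta and whisking
    phase windows on the LFP sample grid — the inputs expected by
    :func:`~thetawhisk.phase_sync.psi_chance_level`.
    """
    from .phase_sync import align_phase_to

    cfg = replace(config, duration_s=window_s + 2 * pad_s)
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    theta_wins, whisk_wins = [], []
    w = EpisodeWindow("win", pad_s, pad_s + window_s)
    for child in ss.spawn(n_trials):
        rng = np.random.default_rng(child)
        lfp, whisk = gen_coupled_pair(cfg, rng)
        pt = instantaneous_phase(bandpass_theta(lfp))
        pw = instantaneous_phase(bandpass_theta(whisk))
        theta_wins.append(pt.window_slice(w))
        whisk_wins.append(align_phase_to(pw, pt, w))
    return np.stack(theta_wins), np.stack(whisk_wins)


# ---------------------------------------------------------------------------
# Spike stage
# ---------------------------------------------------------------------------

def spike_phase_stage(
    bundle: SessionBundle,
    theta_phase: PhaseSeries,
    windows: Sequence[EpisodeWindow],
    conditions: Sequence[str] = ("waiting", "approach", "touch"),
    alpha: float = 0.05,
    min_spikes_fit: int = 10,
) -> dict:
    """Per-condition per-neuron phase-locking fits and population summaries."""
    by_label: dict[str, list[EpisodeWindow]] = {c: [] for c in conditions}
    for w in windows:
        if w.label in by_label:
            by_label[w.label].append(w)
    report: dict = {"conditions": {}, "proportion_tests": {}}
    fits_per_cond: dict[str, list] = {}
    counts: dict[str, tuple[int, int]] = {}
    for cond in conditions:
        fits = []
        n_locked = 0
        for st in bundle.spikes:
            phases = assign_spike_phases(st, theta_phase, by_label[cond])
            if phases.size < min_spikes_fit:
                continue
            fit = fit_von_mises(phases)
            fits.append(fit)
            if fit.p_value < alpha:
                n_locked += 1
        fits_per_cond[cond] = fits
        counts[cond] = (n_locked, len(fits))
        report["conditions"][cond] = population_phase_summary(fits)
    for c1, c2 in zip(conditions, conditions[1:]):
        locked2, total2 = counts[c2]
        locked1, total1 = counts[c1]
        if total1 >= 1 and total2 >= 1:
            try:
                z, p = two_proportion_ztest(locked2, total2, locked1, total1)
                report["proportion_tests"][f"{c2}_vs_{c1}"] = {"z": z, "p": p}
            except ValueError:
                report["proportion_tests"][f"{c2}_vs_{c1}"] = None
    return report


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: SimConfig | dict,
    seed: int | None = None,
    bundle: SessionBundle | None = None,
    n_shuffles: int = 2000,
    n_randomization: int = 10000,
    out_dir=None,
) -> AnalysisReport:
    """Execute every analysis stage on a (simulated or provided) session."""
    if isinstance(config, dict):
        config = SimConfig(**config)
    if seed is not None:
        config = replace(config, seed=seed)
    master = np.random.SeedSequence(config.seed)
    stage_seeds = master.spawn(4)

    if bundle is None:
        bundle = gen_session(config)
    session_end = bundle.lfp.end_time_s
    windows = segment_episodes(bundle.events, session_start_s=bundle.lfp.start_time_s)
    windows += waiting_windows(
        bundle.events, bundle.lfp.start_time_s, session_end
    )

    # --- spectral stage -----------------------------------------------------
    spectral: dict = {"episodes": {}}
    fs = bundle.lfp.sample_rate_hz
    ep_windows: dict[str, list[np.ndarray]] = {}
    for label in ("baseline", "approach", "reward"):
        ep_windows[label] = [
            extract_window(bundle.lfp, w) for w in windows if w.label == label
        ]
    # the touch epoch uses the standard 500 ms interval from contact onset
    ep_windows["touch"] = [
        extract_window(
            bundle.lfp, EpisodeWindow("touch", ev.contact_onset_s, ev.contact_onset_s + 0.5)
        )
        for ev in bundle.events
    ]
    baseline_est = episode_spectrum(ep_windows["baseline"], fs)
    for label, wins in ep_windows.items():
        est = episode_spectrum(wins, fs)
        peak = peak_theta_frequency(est)
        norm = normalize_power(est, baseline_est)
        spectral["episodes"][label] = {
            "peak_frequency_hz": peak.value_hz,
            "peak_tied": peak.tied,
            "n_trials": est.n_trials,
            "mean_theta_power": float(
                est.power[(est.frequencies_hz >= 5) & (est.frequencies_hz <= 12)].mean()
            ),
            "normalized_power": norm.power,
            "frequencies_hz": est.frequencies_hz,
        }
    freqs, pvals, mask, diff = power_randomization_test(
        ep_windows["touch"],
        ep_windows["baseline"],
        fs,
        seed=np.random.default_rng(stage_seeds[0]),
    )
    spectral["touch_vs_baseline"] = {
        "frequencies_hz": freqs,
        "p_values": pvals,
        "significant": mask,
        "mean_power_difference": diff,
    }

    # --- PSI stage ----------------------------------------------------------
    theta_phase, whisk_phase = session_phases(bundle)
    trial_psi = per_trial_psi(bundle, theta_phase, whisk_phase)
    pairs = psi_trial_windows(bundle, theta_phase, whisk_phase, episode="touch")
    null = psi_chance_level(
        pairs, n_shuffles=n_shuffles, seed=np.random.default_rng(stage_seeds[1])
    )
    mean_approach = float(trial_psi["psi_approach"].mean())
    mean_touch = float(trial_psi["psi_touch"].mean())
    touch_results = [
        PSIResult(
            psi=row.psi_touch,
            mean_delay_rad=row.delay_touch,
            n_samples=0,
            episode="touch",
            trial_id=row.trial_id,
        )
        for row in trial_psi.itertuples()
    ]
    try:
        delay_mean, delay_p = phase_delay_stats(
            touch_results, psi_threshold=null.chance_level
        )
        delay_stats = {"mean_delay_rad": delay_mean, "rayleigh_p": delay_p}
    except ValueError:
        delay_stats = None
    psi_report = {
        "mean_psi_approach": mean_approach,
        "mean_psi_touch": mean_touch,
        "chance_level": float(null.chance_level),
        "approach_above_chance": mean_approach > null.chance_level,
        "touch_above_chance": mean_touch > null.chance_level,
        "n_shuffles": null.n_shuffles,
        "touch_delay_stats": delay_stats,
    }

    metrics = trial_metrics(trial_psi)
    behavior = psi_behavior_tests(
        metrics,
        n_randomization=n_randomization,
        seed=np.random.default_rng(stage_seeds[2]),
    )

    # --- spike stage ----------------------------------------------------------
    spikes_report = spike_phase_stage(bundle, theta_phase, windows)

    provenance = {
        "config_hash": config_hash(config),
        "seed": int(config.seed),
        "n_trials": int(config.n_trials),
        "version": __version__,
        "n_shuffles": int(n_shuffles),
        "n_randomization": int(n_randomization),
    }
    report = AnalysisReport(
        provenance=provenance,
        spectral=spectral,
        psi=psi_report,
        metrics=metrics,
        behavior=behavior,
        spikes=spikes_report,
    )
    if out_dir is not None:
        report.save(out_dir)
    return report
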