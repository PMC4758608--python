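"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes: two
noisy narrow-band oscillators in the 5–12 Hz band — a hippocampal-theta-like
LFP and a whisking-angle trace — whose phases evolve as

    dφx = 2π·f_theta·dt + σ·dW,
    dφy = 2π·f_whisk·dt + ε(t)·sin(φx − φy − lag)·dt + σ·dW,

a Kuramoto-style unidirectional sine pull on the whisking phase with
episode-dependent strength ε(t) (stepwise at episode boundaries).  Spike
trains are inhomogeneous Poisson with von Mises phase modulation, and trial
durations/outcomes carry planted links to the within-trial change in phase
synchronization.  Euler–Maruyama integration at the LFP sampling rate keeps
everything bit-reproducible per seed.

Each trial occupies an independent block of the session (fresh random initial
phases, its own child RNG stream): between trials the coupling is zero and
phase noise would decorrelate the oscillators anyway, and independence makes
the across-trial shuffle null exactly exchangeable.  Within a trial the PSI
analysis windows (250 ms either side of contact onset) are integrated first,
so the planted duration/outcome links can be calibrated on the realized PSI
values before the touch tail is generated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import i0 as bessel_i0

from .data_model import (
    ContinuousSignal,
    SessionBundle,
    SpikeTrain,
    TrialEvents,
)
from .phase_sync import PhaseSeries, wrap_phase

TEXTURE_SIDES = {1: "left", 2: "right"}

DEFAULT_EPISODE_GAINS: dict[str, dict[str, float]] = {
    "baseline": {"amplitude": 1.0, "coupling": 0.0},
    "approach": {"amplitude": 1.3, "coupling": 1.2},
    "touch": {"amplitude": 1.6, "coupling": 2.0},
    "turn": {"amplitude": 1.0, "coupling": 0.5},
    "reward": {"amplitude": 0.8, "coupling": 0.0},
    "iti": {"amplitude": 1.0, "coupling": 0.0},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic session generator."""

    duration_s: float = 100.0
    lfp_rate_hz: float = 2000.0
    whisk_rate_hz: float = 1000.0
    f_theta_hz: float = 8.0
    f_whisk_hz: float = 10.0
    #: trial-to-trial SD of the center frequencies (sessions show theta peaks
    #: spread over ~0.25-0.5 Hz and whisking spread over several Hz)
    f_theta_sd_hz: float = 0.4
    f_whisk_sd_hz: float = 1.0
    #: SD (Hz) and correlation time (s) of optional slow Ornstein-Uhlenbeck
    #: wander of each oscillator's instantaneous frequency (off by default;
    #: white phase noise already carries the within-trial variability).
    theta_wander_hz: float = 0.0
    whisk_wander_hz: float = 0.0
    wander_tau_s: float = 0.2
    phase_noise_sd: float = 5.5  # rad/sqrt(s)
    coupling_eps: float = 25.0  # 1/s
    coupling_lag_rad: float = 1.63
    episode_gains: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EPISODE_GAINS.items()}
    )
    kappa_gen: float = 1.0
    theta_gen: float = 2.9
    base_rate_hz: float = 5.0
    n_units: int = 4
    n_trials: int = 100
    behavior_r_target: float = 0.146
    p_correct_link: dict = field(
        default_factory=lambda: {"base": 0.75, "psi_diff": 0.05}
    )
    seed: int = 0
    # trial block layout (seconds)
    trial_period_s: float = 9.0
    contact_lead_s: float = 4.0
    # touch-duration model (study-scale: mean 0.54 s, SD 0.224 s)
    duration_mean_s: float = 0.54
    duration_sd_s: float = 0.224
    duration_clip_s: tuple = (0.05, 2.2)
    turn_mean_s: float = 0.8
    turn_sd_s: float = 0.2
    # signal amplitudes and additive noise
    lfp_amp_uv: float = 100.0
    lfp_noise_sd: float = 25.0  # 1/f (pink) background
    whisk_amp_deg: float = 15.0
    whisk_offset_deg: float = 60.0
    whisk_noise_sd: float = 1.5  # 1/f (pink): postural drift + tracking noise

    def validate(self) -> None:
        scalars = [
            self.duration_s,
            self.lfp_rate_hz,
            self.whisk_rate_hz,
            self.f_theta_hz,
            self.f_whisk_hz,
            self.theta_wander_hz,
            self.whisk_wander_hz,
            self.wander_tau_s,
            self.phase_noise_sd,
            self.coupling_eps,
            self.coupling_lag_rad,
            self.kappa_gen,
            self.base_rate_hz,
        ]
        if not all(np.isfinite(scalars)):
            raise ValueError("SimConfig parameters must all be finite")
        if min(self.lfp_rate_hz, self.whisk_rate_hz, self.base_rate_hz) <= 0:
            raise ValueError("all rates must be positive")
        if self.coupling_eps < 0:
            raise ValueError("coupling_eps must be >= 0")
        if self.kappa_gen < 0:
            raise ValueError("kappa_gen must be >= 0")
        for f in (self.f_theta_hz, self.f_whisk_hz):
            if not (5.0 <= f <= 12.0):
                raise ValueError("center frequencies must lie in the 5-12 Hz band")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        required = (
            self.contact_lead_s
            + self.duration_clip_s[1]
            + (self.turn_mean_s + 2 * self.turn_sd_s)
            + 0.5  # reward
            + 0.5  # slack before the next block
        )
        if self.trial_period_s < required:
            raise ValueError(
                f"infeasible episode layout: trial_period_s must be >= {required:.2f} s"
            )


@njit(cache=False)
def _euler_phases(wx, wy, eps_t, lag, noise_x, noise_y, dt, phi_x0, phi_y0):
    """Euler–Maruyama integration of the coupled phase equations (unwrapped)."""
    n = wx.size
    phx = np.empty(n)
    phy = np.empty(n)
    px = phi_x0
    py = phi_y0
    for i in range(n):
        px = px + wx[i] * dt + noise_x[i]
        py = py + wy[i] * dt + eps_t[i] * np.sin(px - py - lag) * dt + noise_y[i]
        phx[i] = px
        phy[i] = py
    return phx, phy


def _pink_noise(
    n: int, rng: np.random.Generator, sample_rate_hz: float = 2000.0
) -> np.ndarray:
    """Unit-variance 1/f-spectrum noise via spectral shaping.

    The 1/f shaping is floored at 1 Hz (flat below) so that the variance is
    not dominated by drifts slower than any analysis window.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    f = np.maximum(f, 1.0)
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _ou_series(
    n: int, sd: float, tau_s: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck series (exact discretization)."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    alpha = math.exp(-dt / tau_s)
    innov = sd * math.sqrt(1.0 - alpha * alpha) * rng.standard_normal(n)
    x0 = sd * rng.standard_normal()  # stationary initial condition
    out, _ = lfilter([1.0], [1.0, -alpha], innov, zi=np.array([alpha * x0]))
    return out


def _integrate_pair(
    config: SimConfig,
    n_samples: int,
    eps_t: np.ndarray,
    rng: np.random.Generator,
    phi_x0: float,
    phi_y0: float,
) -> tuple[np.ndarray, np.ndarray]:
    dt = 1.0 / config.lfp_rate_hz
    sig = config.phase_noise_sd * math.sqrt(dt)
    noise_x = sig * rng.standard_normal(n_samples)
    noise_y = sig * rng.standard_normal(n_samples)
    wander_x = _ou_series(n_samples, config.theta_wander_hz, config.wander_tau_s, dt, rng)
    wander_y = _ou_series(n_samples, config.whisk_wander_hz, config.wander_tau_s, dt, rng)
    wx = 2.0 * np.pi * (config.f_theta_hz + wander_x)
    wy = 2.0 * np.pi * (config.f_whisk_hz + wander_y)
    return _euler_phases(
        wx, wy, eps_t, config.coupling_lag_rad, noise_x, noise_y, dt, phi_x0, phi_y0
    )


def gen_coupled_pair(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ContinuousSignal, ContinuousSignal]:
    """Generate one theta-like / whisking-like coupled pair of traces.

    Coupling strength is the constant ``config.coupling_eps`` (no episode
    structure).  The LFP trace carries a pink-noise background, the whisking
    trace a white-noise background and a set-point offset.  Identical config
    and seed give bit-identical output.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.lfp_rate_hz
    n = int(round(config.duration_s * fs))
    eps_t = np.full(n, config.coupling_eps)
    phi_x0, phi_y0 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    phx, phy = _integrate_pair(config, n, eps_t, rng, phi_x0, phi_y0)
    lfp = config.lfp_amp_uv * np.cos(phx) + config.lfp_noise_sd * _pink_noise(n, rng, fs)
    ratio = fs / config.whisk_rate_hz
    idx = np.round(np.arange(int(round(config.duration_s * config.whisk_rate_hz))) * ratio).astype(int)
    idx = idx[idx < n]
    whisk = (
        config.whisk_offset_deg
        + config.whisk_amp_deg * np.cos(phy[idx])
        + config.whisk_noise_sd * _pink_noise(idx.size, rng, config.whisk_rate_hz)
    )
    return (
        ContinuousSignal(lfp, fs, 0.0, label="lfp", units="uV"),
        ContinuousSignal(whisk, config.whisk_rate_hz, 0.0, label="whisking", units="degrees"),
    )


def gen_phase_locked_spikes(
    phase: PhaseSeries,
    kappa_gen: float,
    theta_gen: float,
    base_rate_hz: float,
    seed=None,
    unit_id: str = "unit0",
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes with von Mises phase modulation.

    Intensity λ(t) = base_rate · exp(κ·cos(φ(t) − θ)) / I₀(κ); generated by
    thinning (exact for this bounded intensity).  When φ advances uniformly
    the spike-phase distribution is von Mises(θ, κ); κ = 0 gives a homogeneous
    Poisson train with uniform phases.
    """
    if kappa_gen < 0:
        raise ValueError("kappa_gen must be >= 0")
    if base_rate_hz <= 0:
        raise ValueError("base_rate_hz must be > 0")
    rng = np.random.default_rng(seed)
    duration = phase.phases.size / phase.sample_rate_hz
    if duration < 1.0 / phase.band[0]:
        warnings.warn("phase series shorter than one oscillation cycle")
    i0k = float(bessel_i0(kappa_gen))
    lam_max = base_rate_hz * math.exp(kappa_gen) / i0k
    n_cand = rng.poisson(lam_max * duration)
    if n_cand == 0:
        return SpikeTrain(unit_id=unit_id, spike_times_s=np.empty(0))
    t_cand = np.sort(rng.uniform(phase.start_time_s, phase.start_time_s + duration, n_cand))
    unwrapped = np.unwrap(phase.phases)
    t_grid = phase.start_time_s + np.arange(unwrapped.size) / phase.sample_rate_hz
    phi = np.interp(t_cand, t_grid, unwrapped)
    accept = rng.random(n_cand) < np.exp(kappa_gen * (np.cos(phi - theta_gen) - 1.0))
    return SpikeTrain(unit_id=unit_id, spike_times_s=t_cand[accept])


def plant_behavioral_link(
    trial_psi: pd.DataFrame,
    r_target: float,
    p_correct_link: dict | None = None,
    seed=None,
    duration_mean_s: float = 0.54,
    duration_sd_s: float = 0.224,
    duration_clip_s: tuple = (0.05, 2.2),
) -> pd.DataFrame:
    """Plant behavioral outcomes on per-trial PSI values.

    Touch durations are a linear function of the within-trial PSI change plus
    Gaussian noise, calibrated so the Pearson correlation between PSI change
    and *normalized* duration (max − duration) is ``r_target`` in expectation.
    Correct flags are Bernoulli with a linear monotone dependence on PSI-touch,
    calibrated so the correct-minus-incorrect mean PSI-touch difference equals
    ``p_correct_link["psi_diff"]`` in expectation around the base rate
    ``p_correct_link["base"]``.
    """
    if abs(r_target) >= 1:
        raise ValueError("|r_target| must be < 1")
    if p_correct_link is None:
        p_correct_link = {"base": 0.8, "psi_diff": 0.05}
    rng = np.random.default_rng(seed)
    psi_a = trial_psi["psi_approach"].to_numpy(dtype=float)
    psi_t = trial_psi["psi_touch"].to_numpy(dtype=float)
    change = psi_t - psi_a
    n = change.size
    sd = change.std(ddof=0)
    z = (change - change.mean()) / sd if sd > 0 else np.zeros(n)
    noise = rng.standard_normal(n)
    # higher PSI change -> shorter duration -> larger normalized duration
    raw = r_target * z + math.sqrt(1.0 - r_target**2) * noise
    durations = np.clip(
        duration_mean_s - duration_sd_s * raw, duration_clip_s[0], duration_clip_s[1]
    )
    base = float(p_correct_link.get("base", 0.8))
    psi_diff = float(p_correct_link.get("psi_diff", 0.0))
    var_t = psi_t.var(ddof=0)
    if psi_diff != 0.0 and var_t > 0:
        beta = psi_diff * base * (1.0 - base) / var_t
        p_correct = np.clip(base + beta * (psi_t - psi_t.mean()), 0.02, 0.98)
    else:
        p_correct = np.full(n, base)
    correct = rng.random(n) < p_correct
    return pd.DataFrame(
        {
            "touch_duration_s": durations,
            "correct": correct,
            "p_correct": p_correct,
        }
    )


def _episode_bounds(config: SimConfig, onset: float, duration: float, turn: float):
    """(label, start, end) episode spans within one trial block, block-relative."""
    return [
        ("baseline", onset - 3.0, onset - 2.5),
        ("approach", onset - 0.5, onset),
        ("touch", onset, onset + duration),
        ("turn", onset + duration, onset + duration + turn),
        ("reward", onset + duration + turn, onset + duration + turn + 0.5),
    ]


def _gain_profile(
    config: SimConfig,
    n_samples: int,
    fs: float,
    spans: list,
    key: str,
) -> np.ndarray:
    default = config.episode_gains.get("iti", {}).get(key, 1.0 if key == "amplitude" else 0.0)
    prof = np.full(n_samples, default)
    for label, lo, hi in spans:
        g = config.episode_gains.get(label, {}).get(key, default)
        i0 = max(int(round(lo * fs)), 0)
        i1 = min(int(round(hi * fs)), n_samples)
        if i1 > i0:
            prof[i0:i1] = g
    return prof


def _window_psi(phx: np.ndarray, phy: np.ndarray, i0: int, i1: int) -> tuple[float, float]:
    z = np.exp(1j * (phx[i0:i1] - phy[i0:i1])).mean()
    return float(np.abs(z)), float(np.angle(z))


def _measure_head_psi(
    config: SimConfig,
    head_phases: list,
    head_amps: list,
    block_lfp_noise: list,
    block_whisk_noise: list,
    i_onset: int,
    i_split: int,
    i_ext: int,
) -> tuple[np.ndarray, np.ndarray]:
    """PSI of each block head measured through the analysis signal path.

    Builds the noisy LFP/whisking head signals exactly as the assembled
    session will contain them, band-passes them (5-12 Hz zero-phase
    Butterworth), extracts Hilbert phases, aligns the whisking phase onto the
    LFP grid, and returns the windowed PSI over the 250 ms windows before and
    after contact onset.  Planting behavior on these values ties the planted
    links to the PSI observable rather than to the latent true phases.
    """
    from scipy.fft import next_fast_len
    from scipy.signal import butter, hilbert, sosfiltfilt

    from .phase_sync import THETA_BAND

    fs = config.lfp_rate_hz
    fsw = config.whisk_rate_hz
    n_trials = len(head_phases)
    psi_win = i_split - i_onset

    # whisking decimation grid restricted to the head extent
    ratio = fs / fsw
    n_whisk_block = len(block_whisk_noise[0])
    idx_w = np.round(np.arange(n_whisk_block) * ratio).astype(int)
    idx_w = idx_w[idx_w < i_ext]
    n_wh = idx_w.size

    lfp_heads = np.empty((n_trials, i_ext))
    whisk_heads = np.empty((n_trials, n_wh))
    for i in range(n_trials):
        phx, phy = head_phases[i]
        amp = head_amps[i]
        lfp_heads[i] = (
            config.lfp_amp_uv * amp * np.cos(phx) + block_lfp_noise[i][:i_ext]
        )
        whisk_heads[i] = (
            config.whisk_offset_deg
            + config.whisk_amp_deg * amp[idx_w] * np.cos(phy[idx_w])
            + block_whisk_noise[i][:n_wh]
        )

    def _phases(mat: np.ndarray, rate: float) -> np.ndarray:
        sos = butter(4, THETA_BAND, btype="bandpass", fs=rate, output="sos")
        filt = sosfiltfilt(sos, mat, axis=-1)
        npad = min(int(round(rate)), mat.shape[-1] - 1)  # 1 s reflect padding
        padded = np.concatenate(
            [filt[:, npad:0:-1], filt, filt[:, -2 : -npad - 2 : -1]], axis=-1
        )
        nfft = next_fast_len(padded.shape[-1])
        analytic = hilbert(padded, N=nfft, axis=-1)[:, : padded.shape[-1]]
        return np.angle(analytic[:, npad : npad + mat.shape[-1]])

    theta_phase = _phases(lfp_heads, fs)
    whisk_phase = _phases(whisk_heads, fsw)

    t_theta = np.arange(i_onset - psi_win, i_split) / fs
    t_whisk = idx_w / fs
    psi_a = np.empty(n_trials)
    psi_t = np.empty(n_trials)
    for i in range(n_trials):
        wy = np.interp(t_theta, t_whisk, np.unwrap(whisk_phase[i]))
        dphi = theta_phase[i, i_onset - psi_win : i_split] - wy
        z = np.exp(1j * dphi)
        psi_a[i] = np.abs(z[:psi_win].mean())
        psi_t[i] = np.abs(z[psi_win:].mean())
    return psi_a, psi_t


def gen_session(config: SimConfig) -> SessionBundle:
    """Generate a full session: signals, events, spikes, and ground truth.

    Trials are laid out in independent blocks of ``trial_period_s`` seconds
    with contact onset ``contact_lead_s`` into the block.  Coupling (and
    amplitude) is boosted stepwise per episode according to
    ``config.episode_gains``; touch durations and correct flags are planted on
    the realized true-phase PSI values via :func:`plant_behavioral_link`.
    """
    config.validate()
    fs = config.lfp_rate_hz
    P = config.trial_period_s
    n_block = int(round(P * fs))
    dt = 1.0 / fs
    onset_rel = config.contact_lead_s
    psi_win = int(round(0.25 * fs))
    i_onset = int(round(onset_rel * fs))
    i_split = i_onset + psi_win  # integrate blocks up to onset + 250 ms first
    # head extension past the touch window: filter context for the plant-time
    # PSI measurement (touch-gain coupling is assumed to continue there)
    pad = int(round(0.625 * fs))
    i_ext = min(i_split + pad, n_block)

    ss = np.random.SeedSequence(config.seed)
    trial_seeds = ss.spawn(config.n_trials)
    aux_rng = np.random.default_rng(ss.spawn(1)[0])

    n_trials = config.n_trials
    trial_rngs = [np.random.default_rng(s) for s in trial_seeds]
    n_whisk_block = int(round(P * config.whisk_rate_hz))
    head_phases = []
    head_amps = []
    block_lfp_noise = []
    block_whisk_noise = []
    psi_a = np.empty(n_trials)
    psi_t = np.empty(n_trials)
    delay_t = np.empty(n_trials)
    sig = config.phase_noise_sd * math.sqrt(dt)

    # pass 1: integrate each block through contact + 250 ms
    head_noise_states = []
    f_theta_i = np.empty(n_trials)
    f_whisk_i = np.empty(n_trials)
    for i in range(n_trials):
        rng = trial_rngs[i]
        f_theta_i[i] = np.clip(
            rng.normal(config.f_theta_hz, config.f_theta_sd_hz), 5.0, 12.0
        )
        f_whisk_i[i] = np.clip(
            rng.normal(config.f_whisk_hz, config.f_whisk_sd_hz), 5.0, 12.0
        )
        phi0 = rng.uniform(0.0, 2.0 * np.pi, size=2)
        noise = sig * rng.standard_normal((2, n_block))
        wander = np.vstack(
            [
                _ou_series(n_block, config.theta_wander_hz, config.wander_tau_s, dt, rng),
                _ou_series(n_block, config.whisk_wander_hz, config.wander_tau_s, dt, rng),
            ]
        )
        spans_head = [
            ("baseline", onset_rel - 3.0, onset_rel - 2.5),
            ("approach", onset_rel - 0.5, onset_rel),
            ("touch", onset_rel, i_ext / fs),
        ]
        eps_head = config.coupling_eps * _gain_profile(
            config, i_ext, fs, spans_head, "coupling"
        )
        wx = 2.0 * np.pi * (f_theta_i[i] + wander[0, :i_ext])
        wy = 2.0 * np.pi * (f_whisk_i[i] + wander[1, :i_ext])
        phx, phy = _euler_phases(
            wx,
            wy,
            eps_head,
            config.coupling_lag_rad,
            noise[0, :i_ext],
            noise[1, :i_ext],
            dt,
            phi0[0],
            phi0[1],
        )
        amp_head = _gain_profile(config, i_ext, fs, spans_head, "amplitude")
        head_phases.append((phx, phy))
        head_noise_states.append((noise, wander))
        head_amps.append(amp_head)
        # per-block background noise (reused verbatim when the session signals
        # are assembled, so the plant-time measurement sees the final signals)
        block_lfp_noise.append(
            config.lfp_noise_sd * _pink_noise(n_block, rng, fs)
        )
        block_whisk_noise.append(
            config.whisk_noise_sd
            * _pink_noise(n_whisk_block, rng, config.whisk_rate_hz)
        )
        psi_a[i], _ = _window_psi(phx, phy, i_onset - psi_win, i_onset)
        psi_t[i], delay_t[i] = _window_psi(phx, phy, i_onset, i_split)

    # measure the head PSI values through the actual analysis path (additive
    # noise, 5-12 Hz zero-phase bandpass, Hilbert phase) so that behavioral
    # links are planted on the PSI observable itself
    psi_a_meas, psi_t_meas = _measure_head_psi(
        config,
        head_phases,
        head_amps,
        block_lfp_noise,
        block_whisk_noise,
        i_onset,
        i_split,
        i_ext,
    )

    # plant durations and outcomes on the plant-time measured PSI values
    outcomes = plant_behavioral_link(
        pd.DataFrame({"psi_approach": psi_a_meas, "psi_touch": psi_t_meas}),
        r_target=config.behavior_r_target,
        p_correct_link=config.p_correct_link,
        seed=aux_rng,
        duration_mean_s=config.duration_mean_s,
        duration_sd_s=config.duration_sd_s,
        duration_clip_s=config.duration_clip_s,
    )
    durations = outcomes["touch_duration_s"].to_numpy()
    turns = np.clip(
        aux_rng.normal(config.turn_mean_s, config.turn_sd_s, n_trials),
        0.3,
        config.turn_mean_s + 2 * config.turn_sd_s,
    )

    # pass 2: integrate each block's tail with the realized touch interval
    phx_all = np.empty(n_trials * n_block)
    phy_all = np.empty(n_trials * n_block)
    amp_x = np.empty(n_trials * n_block)
    amp_y = np.empty(n_trials * n_block)
    events = []
    rewarded_side = TEXTURE_SIDES
    for i in range(n_trials):
        rng = trial_rngs[i]
        noise, wander = head_noise_states[i]
        spans = _episode_bounds(config, onset_rel, float(durations[i]), float(turns[i]))
        eps_full = config.coupling_eps * _gain_profile(config, n_block, fs, spans, "coupling")
        # contact-evoked coupling/amplitude boosts persist through the fixed
        # post-contact context [onset, i_ext) even when the touch itself is
        # shorter: engagement does not switch off with contact offset, and it
        # keeps the assembled signals identical to the plant-time head signals
        eps_full[i_onset:i_ext] = (
            config.coupling_eps * config.episode_gains["touch"]["coupling"]
        )
        phx_h, phy_h = head_phases[i]
        wx = 2.0 * np.pi * (f_theta_i[i] + wander[0, i_split:])
        wy = 2.0 * np.pi * (f_whisk_i[i] + wander[1, i_split:])
        phx_t, phy_t = _euler_phases(
            wx,
            wy,
            eps_full[i_split:],
            config.coupling_lag_rad,
            noise[0, i_split:],
            noise[1, i_split:],
            dt,
            phx_h[i_split - 1],
            phy_h[i_split - 1],
        )
        lo = i * n_block
        phx_all[lo : lo + i_split] = phx_h[:i_split]
        phx_all[lo + i_split : lo + n_block] = phx_t
        phy_all[lo : lo + i_split] = phy_h[:i_split]
        phy_all[lo + i_split : lo + n_block] = phy_t
        amp_x[lo : lo + n_block] = _gain_profile(config, n_block, fs, spans, "amplitude")
        amp_x[lo + i_onset : lo + i_ext] = config.episode_gains["touch"]["amplitude"]
        amp_y[lo : lo + n_block] = amp_x[lo : lo + n_block]

        t0 = i * P
        texture = int(aux_rng.integers(1, 3))
        correct = bool(outcomes["correct"].iloc[i])
        side = rewarded_side[texture]
        choice = side if correct else ("left" if side == "right" else "right")
        events.append(
            TrialEvents(
                trial_id=i,
                contact_onset_s=t0 + onset_rel,
                contact_offset_s=t0 + onset_rel + float(durations[i]),
                spout_arrival_s=t0 + onset_rel + float(durations[i]) + float(turns[i]),
                reward_end_s=t0 + onset_rel + float(durations[i]) + float(turns[i]) + 0.5,
                texture_id=texture,
                choice_side=choice,
                correct=correct,
            )
        )

    # the per-block background noise drawn in pass 1 is reused verbatim so the
    # assembled signals coincide with what the plant-time measurement saw
    lfp = ContinuousSignal(
        config.lfp_amp_uv * amp_x * np.cos(phx_all) + np.concatenate(block_lfp_noise),
        fs,
        0.0,
        label="lfp",
        units="uV",
    )
    ratio = fs / config.whisk_rate_hz
    idx_w = np.round(np.arange(n_whisk_block) * ratio).astype(int)
    idx_w = idx_w[idx_w < n_block]
    whisk_samples = np.empty(n_trials * idx_w.size)
    for i in range(n_trials):
        lo = i * n_block
        wlo = i * idx_w.size
        whisk_samples[wlo : wlo + idx_w.size] = (
            config.whisk_offset_deg
            + config.whisk_amp_deg * amp_y[lo + idx_w] * np.cos(phy_all[lo + idx_w])
            + block_whisk_noise[i][: idx_w.size]
        )
    whisk = ContinuousSignal(
        whisk_samples,
        config.whisk_rate_hz,
        0.0,
        label="whisking",
        units="degrees",
    )

    # phase-locked spikes referenced to the true theta phase
    true_theta_phase = PhaseSeries(wrap_phase(phx_all), fs, 0.0)
    spikes = []
    unit_rngs = np.random.SeedSequence(config.seed + 1).spawn(config.n_units)
    for u in range(config.n_units):
        urng = np.random.default_rng(unit_rngs[u])
        theta_u = config.theta_gen + urng.uniform(-0.4, 0.4)
        spikes.append(
            gen_phase_locked_spikes(
                true_theta_phase,
                kappa_gen=config.kappa_gen,
                theta_gen=theta_u,
                base_rate_hz=config.base_rate_hz,
                seed=urng,
                unit_id=f"unit{u}",
            )
        )

    truth = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "psi_approach_true": psi_a,
            "psi_touch_true": psi_t,
            "psi_change_true": psi_t - psi_a,
            "psi_approach_meas": psi_a_meas,
            "psi_touch_meas": psi_t_meas,
            "mean_delay_touch_true": delay_t,
            "touch_duration_s": durations,
            "correct": outcomes["correct"].to_numpy(),
            "p_correct": outcomes["p_correct"].to_numpy(),
        }
    )
    cfg = replace(config, duration_s=n_trials * P)
    bundle = SessionBundle(lfp=lfp, whisking=whisk, spikes=spikes, events=events, truth=truth)
    bundle.config = cfg  # provenance for downstream stages
    return bundle
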