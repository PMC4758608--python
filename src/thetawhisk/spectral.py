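"""Time–frequency and episode power spectra with shuffle-based significance.

Two estimators are provided: an adaptive spectrogram whose window at each
frequency f is eight cycles long (Δt = 8/f) and tapered with Slepian (DPSS)
sequences, and fixed-length episode spectra from Hanning-tapered periodograms
on a 4–20 Hz grid.  Episode spectra are zero-padded to an effective 0.25 Hz
grid so that theta peak frequencies resolve at quarter-hertz precision.
Group differences in power are tested per frequency with an across-trial
shuffle (randomization) test, Bonferroni-corrected over frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from scipy.signal.windows import dpss

from .data_model import ContinuousSignal

F_RANGE_HZ = (4.0, 20.0)
THETA_RANGE_HZ = (5.0, 12.0)


@dataclass
class SpectralEstimate:
    """Per-trial power spectra and their mean on a fixed frequency grid."""

    frequencies_hz: np.ndarray
    power: np.ndarray  # mean across trials
    per_trial: np.ndarray  # (n_trials, n_freqs)
    taper: str = "hanning"
    normalization: str = "raw"

    @property
    def n_trials(self) -> int:
        return self.per_trial.shape[0]


@dataclass
class PeakFrequency:
    value_hz: float
    band: tuple[float, float] = THETA_RANGE_HZ
    tied: bool = False


def episode_spectrum(
    windows,
    sample_rate_hz: float,
    f_range: tuple[float, float] = F_RANGE_HZ,
    df: float = 0.25,
) -> SpectralEstimate:
    """Hanning-tapered periodograms of equal-length episode windows.

    ``windows`` is a sequence of equal-length sample arrays (one per trial);
    spectra are zero-padded to an effective ``df`` grid spacing and restricted
    to ``f_range``.  Unequal window lengths are an error: spectral comparisons
    require all epochs to be of equal length.
    """
    arrays = [np.asarray(w, dtype=np.float64) for w in windows]
    if not arrays:
        raise ValueError("need at least one window")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all episode windows must have equal length")
    nfft = max(int(round(sample_rate_hz / df)), n)
    X = np.stack(arrays)
    freqs, power = periodogram(
        X, fs=sample_rate_hz, window="hann", nfft=nfft, detrend=False, axis=-1
    )
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    per_trial = power[:, sel]
    return SpectralEstimate(
        frequencies_hz=freqs[sel],
        power=per_trial.mean(axis=0),
        per_trial=per_trial,
        taper="hanning",
        normalization="raw",
    )


def normalize_power(
    estimate: SpectralEstimate, baseline_estimate: SpectralEstimate
) -> SpectralEstimate:
    """Normalize log power by the 4 Hz baseline log power.

    Each value 10·log10(power) is divided by the baseline's 10·log10(power at
    4 Hz), the convention used for grand-averaging episode spectra across
    subjects.  A non-positive (or unit) baseline power at 4 Hz is an error.
    """
    idx = int(np.argmin(np.abs(baseline_estimate.frequencies_hz - 4.0)))
    if abs(baseline_estimate.frequencies_hz[idx] - 4.0) > 0.26:
        raise ValueError("baseline estimate lacks a 4 Hz bin")
    p4 = baseline_estimate.power[idx]
    if p4 <= 0:
        raise ValueError("non-positive baseline power at 4 Hz")
    denom = 10.0 * np.log10(p4)
    if denom == 0:
        raise ValueError("baseline power at 4 Hz gives zero log power")
    with np.errstate(divide="ignore"):
        per_trial = 10.0 * np.log10(estimate.per_trial) / denom
        mean = 10.0 * np.log10(estimate.power) / denom
    return SpectralEstimate(
        frequencies_hz=estimate.frequencies_hz,
        power=mean,
        per_trial=per_trial,
        taper=estimate.taper,
        normalization="baseline_4hz_log",
    )


def peak_theta_frequency(
    estimate: SpectralEstimate, band: tuple[float, float] = THETA_RANGE_HZ
) -> PeakFrequency:
    """Frequency of maximum mean power within the theta band.

    Ties are broken to the lowest frequency and flagged.
    """
    sel = (estimate.frequencies_hz >= band[0]) & (estimate.frequencies_hz <= band[1])
    if not np.any(sel):
        raise ValueError("frequency grid does not cover the theta band")
    freqs = estimate.frequencies_hz[sel]
    power = estimate.power[sel]
    best = np.max(power)
    at_best = np.flatnonzero(power == best)
    return PeakFrequency(
        value_hz=float(freqs[at_best[0]]), band=band, tied=at_best.size > 1
    )


def spectrogram_adaptive(
    signal: ContinuousSignal,
    contact_times_s,
    t_range_s: float = 3.0,
    f_grid_hz: np.ndarray | None = None,
    step_s: float = 0.05,
    n_tapers: int = 3,
    nw: float = 2.0,
    baseline_s: tuple[float, float] = (-3.0, -2.5),
    normalization: str = "ratio",
):
    """Adaptive multitaper spectrogram around contact onset, baseline-normalized.

    At each frequency f the analysis window is eight cycles long (Δt = 8/f),
    multiplied by ``n_tapers`` Slepian tapers (time–bandwidth NW = ``nw``), and
    power is evaluated at f by direct discrete Fourier projection.  Power is
    averaged over trials and normalized per frequency to the mean power in the
    pre-contact baseline interval, either as a ratio (default) or as a dB
    difference (``normalization="db"``).

    Returns ``(t_grid, f_grid, P)`` with P of shape (n_freqs, n_times); trials
    without ±``t_range_s`` (plus the longest window) of signal coverage are
    dropped with a warning.
    """
    import warnings

    if f_grid_hz is None:
        f_grid_hz = np.arange(F_RANGE_HZ[0], F_RANGE_HZ[1] + 1e-9, 0.5)
    f_grid_hz = np.asarray(f_grid_hz, dtype=np.float64)
    fs = signal.sample_rate_hz
    t_grid = np.arange(-t_range_s, t_range_s + 1e-9, step_s)
    max_half = 4.0 / f_grid_hz.min()  # half of the longest (lowest-f) window

    usable = []
    for tc in np.atleast_1d(contact_times_s):
        if (
            tc - t_range_s - max_half >= signal.start_time_s
            and tc + t_range_s + max_half <= signal.end_time_s
        ):
            usable.append(float(tc))
        else:
            warnings.warn(f"trial at {tc:.2f}s lacks +/-{t_range_s}s coverage; dropped")
    if not usable:
        raise ValueError("no trial has sufficient signal coverage")

    P = np.zeros((f_grid_hz.size, t_grid.size))
    x = signal.samples
    t0 = signal.start_time_s
    for fi, f in enumerate(f_grid_hz):
        wlen = int(round(8.0 / f * fs))
        if wlen < 8 or wlen > x.size:
            P[fi] = np.nan
            continue
        tapers = dpss(wlen, nw, n_tapers)  # (n_tapers, wlen)
        # complex projection vectors at frequency f, one per taper
        tt = np.arange(wlen) / fs
        carriers = tapers * np.exp(-2j * np.pi * f * tt)[None, :]
        for tc in usable:
            centers = ((tc + t_grid - t0) * fs).round().astype(int)
            starts = centers - wlen // 2
            seg = np.stack([x[s : s + wlen] for s in starts])
            coeffs = seg @ carriers.T  # (n_times, n_tapers)
            P[fi] += (np.abs(coeffs) ** 2).mean(axis=1)
    P /= len(usable)

    base_sel = (t_grid >= baseline_s[0]) & (t_grid <= baseline_s[1])
    if normalization != "raw" and not np.any(base_sel):
        raise ValueError(
            f"baseline interval {baseline_s} contains no time-grid points; "
            f"increase t_range_s or move the baseline"
        )
    base = P[:, base_sel].mean(axis=1, keepdims=True) if np.any(base_sel) else None
    if normalization == "ratio":
        P = P / base
    elif normalization == "db":
        P = 10.0 * (np.log10(P) - np.log10(base))
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return t_grid, f_grid_hz, P


def power_randomization_test(
    windows_a,
    windows_b,
    sample_rate_hz: float,
    n_shuffles: int = 1000,
    seed=None,
    alpha: float = 0.05,
    df: float = 0.5,
    f_range: tuple[float, float] = F_RANGE_HZ,
):
    """Per-frequency shuffle test for a power difference between two groups.

    The statistic is the difference of group-mean power at each frequency;
    shuffles permute window-to-group assignment across all trials.  Two-sided
    p-values use the add-one rule; the significance mask applies Bonferroni
    correction over the frequency grid (``p < alpha / n_freqs``).

    Returns ``(frequencies, p_values, significant_mask, observed_diff)``.
    """
    import warnings

    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives unstable p-values")
    a = episode_spectrum(windows_a, sample_rate_hz, f_range=f_range, df=df)
    b = episode_spectrum(windows_b, sample_rate_hz, f_range=f_range, df=df)
    if a.n_trials < 2 or b.n_trials < 2:
        raise ValueError("need at least 2 windows per group")
    pooled = np.vstack([a.per_trial, b.per_trial])
    n_a = a.n_trials
    observed = a.power - b.power
    rng = np.random.default_rng(seed)
    n_total = pooled.shape[0]
    idx = np.argsort(rng.random((n_shuffles, n_total)), axis=1)
    shuffled = pooled[idx]  # (n_shuffles, n_total, n_freqs)
    diffs = shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1)
    exceed = np.sum(np.abs(diffs) >= np.abs(observed)[None, :] - 1e-15, axis=0)
    p = (1 + exceed) / (n_shuffles + 1)
    mask = p < alpha / a.frequencies_hz.size
    return a.frequencies_hz, p, mask, observed
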