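"""Theta-band phase extraction and phase-synchronization analysis.

Both signals are band-passed to 5–12 Hz with a zero-phase Butterworth filter,
given instantaneous phases via the Hilbert transform (phase 0 at signal maxima,
so for whisking angle phase 0 is peak protraction), optionally remapped with a
rank-based transform that removes wave-shape asymmetry bias, and compared by
the Phase Synchronization Index

    PSI = sqrt(<cos θxy>² + <sin θxy>²),   θxy(t) = n·φx(t) − m·φy(t),

the mean resultant length of the 1:1 phase difference over an analysis window
(0 = no locking, 1 = constant phase difference).  Chance levels come from
2,000 across-trial shuffle sets; behavioral coupling statistics relate the
within-trial PSI change (touch − approach) to trial speed and outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.stats import pearsonr, rankdata, ttest_ind, wilcoxon

from .data_model import ContinuousSignal, EpisodeWindow
from .spike_phase import rayleigh_test, resultant, wrap_phase

THETA_BAND = (5.0, 12.0)
#: common PSI window length across approach and touch episodes
PSI_WINDOW_S = 0.25
#: trial-duration exclusion bounds (outliers reflect an altered strategy)
DURATION_BOUNDS_S = (0.15, 2.0)


@dataclass
class PhaseSeries:
    """Instantaneous phase (rad, wrapped to (−π, π]) of a band-passed signal."""

    phases: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0
    band: tuple[float, float] = THETA_BAND
    bias_corrected: bool = False

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.phases.size) / self.sample_rate_hz

    def window_slice(self, window: EpisodeWindow) -> np.ndarray:
        i0 = int(round((window.start_s - self.start_time_s) * self.sample_rate_hz))
        n = int(round(window.duration_s * self.sample_rate_hz))
        if i0 < 0 or i0 + n > self.phases.size:
            raise ValueError("window outside phase coverage")
        return self.phases[i0 : i0 + n]


@dataclass
class PSIResult:
    psi: float
    mean_delay_rad: float
    n_samples: int
    episode: str = ""
    trial_id: int | None = None

    def __post_init__(self) -> None:
        assert -1e-12 <= self.psi <= 1.0 + 1e-12


@dataclass
class ShuffleNull:
    """Across-trial shuffle distribution of set-mean PSI and its chance level."""

    shuffled_psi: np.ndarray
    chance_level: float
    n_shuffles: int
    method: str = "percentile"


# ---------------------------------------------------------------------------
# Filtering and phase extraction
# ---------------------------------------------------------------------------

def bandpass_theta(
    signal: ContinuousSignal,
    band: tuple[float, float] = THETA_BAND,
    order: int = 4,
) -> ContinuousSignal:
    """Zero-phase (forward–backward) Butterworth band-pass, same length/rate."""
    fs = signal.sample_rate_hz
    if fs <= 2 * band[1]:
        raise ValueError(f"sample rate {fs} Hz too low for band top {band[1]} Hz")
    # require a few filter time constants of data for a stable two-pass filter
    if signal.samples.size < 3 * int(fs / band[0]):
        raise ValueError("signal too short for stable band-pass filtering")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, signal.samples)
    return ContinuousSignal(
        samples=filtered,
        sample_rate_hz=fs,
        start_time_s=signal.start_time_s,
        label=signal.label,
        units=signal.units,
    )


def instantaneous_phase(
    filtered: ContinuousSignal, pad_s: float = 1.0
) -> PhaseSeries:
    """Analytic-signal phase of a band-passed trace, wrapped to (−π, π].

    Phase 0 falls at signal maxima (cosine convention).  The trace is
    reflect-padded ``pad_s`` seconds at each end before the Hilbert transform
    to suppress edge effects; analysis windows should stay >= 0.25 s from the
    signal edges.
    """
    x = filtered.samples
    if np.ptp(x) == 0:
        raise ValueError("constant signal has undefined phase")
    fs = filtered.sample_rate_hz
    npad = min(int(round(pad_s * fs)), x.size - 1)
    padded = np.concatenate([x[npad:0:-1], x, x[-2 : -npad - 2 : -1]])
    from scipy.fft import next_fast_len

    nfft = next_fast_len(padded.size)
    analytic = hilbert(padded, N=nfft)[: padded.size]
    phases = wrap_phase(np.angle(analytic[npad : npad + x.size]))
    return PhaseSeries(
        phases=phases,
        sample_rate_hz=fs,
        start_time_s=filtered.start_time_s,
        bias_corrected=False,
    )


def psi_bias_correct(
    phase: PhaseSeries, alpha: float = 0.05, min_samples: int = 100
) -> PhaseSeries:
    """Remove wave-shape asymmetry bias by a rank (empirical-CDF) remap.

    If the session-wide phase distribution departs from uniformity (Rayleigh
    test at ``alpha``), phases are remapped by Ψ(φ) = 2π·F̂(φ) − π where F̂ is
    the session's empirical distribution of phase; the output distribution is
    uniform by construction.  Otherwise (or with fewer than ``min_samples``
    phases) the series is returned unchanged with ``bias_corrected=False``.
    """
    phi = phase.phases
    if phi.size < min_samples:
        return phase
    _, p = rayleigh_test(phi)
    if p >= alpha:
        return PhaseSeries(
            phases=phi,
            sample_rate_hz=phase.sample_rate_hz,
            start_time_s=phase.start_time_s,
            band=phase.band,
            bias_corrected=False,
        )
    ranks = rankdata(phi, method="average")
    remapped = wrap_phase(2.0 * np.pi * ranks / phi.size - np.pi)
    return PhaseSeries(
        phases=remapped,
        sample_rate_hz=phase.sample_rate_hz,
        start_time_s=phase.start_time_s,
        band=phase.band,
        bias_corrected=True,
    )


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def align_phase_to(
    phase_y: PhaseSeries, phase_x: PhaseSeries, window: EpisodeWindow
) -> np.ndarray:
    """Phase of y at x's sample times inside ``window``, via linear
    interpolation of the unwrapped phase (handles differing sample rates)."""
    fs_x = phase_x.sample_rate_hz
    i0 = int(round((window.start_s - phase_x.start_time_s) * fs_x))
    n = int(round(window.duration_s * fs_x))
    t_x = phase_x.start_time_s + (i0 + np.arange(n)) / fs_x
    # unwrap y only over a margin around the window for efficiency
    fs_y = phase_y.sample_rate_hz
    j0 = int(np.floor((window.start_s - phase_y.start_time_s) * fs_y)) - 2
    j1 = int(np.ceil((window.end_s - phase_y.start_time_s) * fs_y)) + 2
    j0 = max(j0, 0)
    j1 = min(j1, phase_y.phases.size)
    if j1 - j0 < 2:
        raise ValueError("window outside phase coverage of y")
    seg = np.unwrap(phase_y.phases[j0:j1])
    t_y = phase_y.start_time_s + (j0 + np.arange(j1 - j0)) / fs_y
    return wrap_phase(np.interp(t_x, t_y, seg))


def compute_psi(
    phase_x: PhaseSeries,
    phase_y: PhaseSeries,
    window: EpisodeWindow,
    n: int = 1,
    m: int = 1,
    episode: str = "",
    trial_id: int | None = None,
) -> PSIResult:
    """PSI and mean phase delay of θxy = n·φx − m·φy over ``window``.

    φx is the theta (LFP) phase and φy the whisking phase, so the reported
    delay is theta-minus-whisking.  Only 1:1 locking is used by the pipeline.
    """
    px = phase_x.window_slice(window)
    if (
        phase_y.sample_rate_hz == phase_x.sample_rate_hz
        and phase_y.start_time_s == phase_x.start_time_s
    ):
        py = phase_y.window_slice(window)
    else:
        py = align_phase_to(phase_y, phase_x, window)
    if px.size < 2:
        raise ValueError("PSI window must contain at least 2 samples")
    theta_xy = wrap_phase(n * px - m * py)
    r, delay = resultant(theta_xy)
    return PSIResult(
        psi=r,
        mean_delay_rad=delay,
        n_samples=int(px.size),
        episode=episode or window.label,
        trial_id=trial_id if trial_id is not None else window.trial_id,
    )


def pairwise_psi_matrix(theta_windows: np.ndarray, whisk_windows: np.ndarray) -> np.ndarray:
    """PSI of every (theta trial i, whisking trial j) pairing.

    Both inputs are (n_trials, n_samples) phase arrays on a common time grid.
    Entry (i, j) is |mean_t exp(i(φx_i − φy_j))|, computed with one complex
    matrix product.
    """
    theta_windows = np.asarray(theta_windows)
    E = np.exp(1j * theta_windows)
    F = np.exp(-1j * np.asarray(whisk_windows))
    return np.abs(E @ F.T) / theta_windows.shape[1]


def _derangements(n: int, n_shuffles: int, rng: np.random.Generator) -> np.ndarray:
    perms = np.empty((n_shuffles, n), dtype=np.intp)
    for k in range(n_shuffles):
        while True:
            p = rng.permutation(n)
            if not np.any(p == np.arange(n)):
                perms[k] = p
                break
    return perms


def psi_chance_level(
    trial_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    n_shuffles: int = 2000,
    seed=None,
    method: str = "percentile",
) -> ShuffleNull:
    """Shuffle-based chance level for the session-mean PSI.

    Each of ``n_shuffles`` sets pairs the theta phase window of trial i with the
    whisking phase window of a deranged trial j ≠ i and records the set-mean
    PSI.  ``chance_level`` is the 97.5th percentile of set means
    (``method="percentile"``) or mean + 1.96·SD (``method="normal"``).
    """
    n = len(trial_pairs)
    if n < 10:
        raise ValueError("chance level requires at least 10 trials")
    lengths = {p[0].shape[-1] for p in trial_pairs} | {p[1].shape[-1] for p in trial_pairs}
    if len(lengths) != 1:
        raise ValueError("all trial windows must share one length")
    theta = np.stack([p[0] for p in trial_pairs])
    whisk = np.stack([p[1] for p in trial_pairs])
    M = pairwise_psi_matrix(theta, whisk)
    rng = np.random.default_rng(seed)
    perms = _derangements(n, n_shuffles, rng)
    set_means = M[np.arange(n)[None, :], perms].mean(axis=1)
    if method == "percentile":
        chance = float(np.percentile(set_means, 97.5))
    elif method == "normal":
        chance = float(set_means.mean() + 1.96 * set_means.std(ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return ShuffleNull(
        shuffled_psi=set_means, chance_level=chance, n_shuffles=n_shuffles, method=method
    )


def phase_delay_stats(
    trial_results: Sequence[PSIResult],
    psi_threshold: float | None = None,
) -> tuple[float, float]:
    """Circular mean of per-trial phase delays and Rayleigh p for clustering.

    With ``psi_threshold`` only trials whose PSI exceeds it (i.e. exceed the
    95% confidence chance level) enter the test.
    """
    delays = np.array(
        [
            res.mean_delay_rad
            for res in trial_results
            if psi_threshold is None or res.psi > psi_threshold
        ]
    )
    if delays.size < 5:
        raise ValueError("fewer than 5 trials available for phase-delay statistics")
    _, p = rayleigh_test(delays)
    _, mean = resultant(delays)
    return mean, p


# ---------------------------------------------------------------------------
# Trial metrics and behavior statistics
# ---------------------------------------------------------------------------

def trial_metrics(
    trials: pd.DataFrame,
    rat_col: str | None = None,
    duration_bounds_s: tuple[float, float] = DURATION_BOUNDS_S,
) -> pd.DataFrame:
    """Per-trial behavioral/PSI metrics table.

    ``trials`` needs columns ``trial_id, psi_approach, psi_touch,
    touch_duration_s, correct`` (plus a rat identifier column if more than one
    animal).  Adds ``psi_change``, ``normalized_duration`` (per-rat maximum
    duration − trial duration, higher = speedier), exclusion flags for
    durations outside ``duration_bounds_s``, and the duration / PSI groupings:
    duration groups split at per-rat mean ± 0.4·SD, PSI groups at mean ± 0.5·SD.
    Group statistics are computed over non-excluded trials.
    """
    df = trials.copy()
    required = {"trial_id", "psi_approach", "psi_touch", "touch_duration_s", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    if rat_col is None:
        df["_rat"] = 0
        rat_col = "_rat"
    df["psi_change"] = df["psi_touch"] - df["psi_approach"]
    lo, hi = duration_bounds_s
    df["excluded"] = (df["touch_duration_s"] < lo) | (df["touch_duration_s"] > hi)

    def _per_rat(g: pd.DataFrame) -> pd.DataFrame:
        ok = g.loc[~g["excluded"]]
        if ok.empty:
            raise ValueError("a rat has no non-excluded trials (missing per-rat maximum)")
        dmax = ok["touch_duration_s"].max()
        g = g.copy()
        g["normalized_duration"] = dmax - g["touch_duration_s"]
        dm, ds = ok["touch_duration_s"].mean(), ok["touch_duration_s"].std(ddof=1)
        g["duration_group"] = np.select(
            [
                g["touch_duration_s"] < dm - 0.4 * ds,
                g["touch_duration_s"] > dm + 0.4 * ds,
            ],
            ["fast", "slow"],
            default="intermediate",
        )
        for col in ("psi_approach", "psi_touch"):
            m, s = ok[col].mean(), ok[col].std(ddof=1)
            g[f"{col}_group"] = np.select(
                [g[col] < m - 0.5 * s, g[col] > m + 0.5 * s],
                ["low", "high"],
                default="intermediate",
            )
        return g

    df = (
        df.groupby(rat_col, group_keys=False)[df.columns]
        .apply(_per_rat)
        .reset_index(drop=True)
    )
    if rat_col == "_rat":
        df = df.drop(columns="_rat")
    return df


def two_sample_randomization_test(
    a: np.ndarray,
    b: np.ndarray,
    n_iter: int = 10000,
    seed=None,
) -> tuple[float, float]:
    """Two-sided randomization test on the difference of group means.

    Returns ``(observed difference a−b, p)`` with the add-one rule so p is
    never exactly 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = a.mean() - b.mean()
    # vectorized label shuffles
    idx = np.argsort(rng.random((n_iter, pooled.size)), axis=1)
    shuffled = pooled[idx]
    diffs = shuffled[:, :n_a].mean(axis=1) - shuffled[:, n_a:].mean(axis=1)
    p = (1 + int(np.sum(np.abs(diffs) >= abs(observed) - 1e-15))) / (n_iter + 1)
    return float(observed), float(p)


def psi_behavior_tests(
    metrics: pd.DataFrame,
    n_randomization: int = 10000,
    seed=None,
) -> dict:
    """All PSI-versus-behavior statistics on a trial-metrics table.

    (a) Pearson r between PSI change and normalized duration, overall and
    conditional on PSI-approach / PSI-touch groups; (b) Wilcoxon signed-rank
    on paired (PSI-approach, PSI-touch) within each duration group; (c)
    two-sample randomization test of PSI-touch on correct vs incorrect trials;
    (d) one-tail t-tests on PSI change (correct > incorrect, and fast vs
    intermediate vs slow).  Groups with fewer than 3 trials are skipped and
    flagged.  Excluded trials are dropped first.
    """
    rng = np.random.default_rng(seed)
    ok = metrics.loc[~metrics["excluded"]].reset_index(drop=True)
    if len(ok) < 10:
        raise ValueError("need at least 10 non-excluded trials")
    report: dict = {"n_trials": int(len(ok)), "skipped": []}

    def _pearson(sub: pd.DataFrame) -> dict | None:
        if len(sub) < 3:
            return None
        r, p = pearsonr(sub["psi_change"], sub["normalized_duration"])
        return {"r": float(r), "p": float(p), "n": int(len(sub))}

    report["correlation_overall"] = _pearson(ok)
    for col in ("psi_approach_group", "psi_touch_group"):
        report[f"correlation_by_{col}"] = {}
        for grp, sub in ok.groupby(col):
            res = _pearson(sub)
            if res is None:
                report["skipped"].append(f"correlation {col}={grp}")
            else:
                report[f"correlation_by_{col}"][grp] = res

    report["wilcoxon_by_duration_group"] = {}
    for grp, sub in ok.groupby("duration_group"):
        if len(sub) < 3:
            report["skipped"].append(f"wilcoxon duration_group={grp}")
            continue
        diffs = (sub["psi_touch"] - sub["psi_approach"]).to_numpy()
        if np.allclose(diffs, 0.0):
            stat, p = np.nan, 1.0
        else:
            stat, p = wilcoxon(sub["psi_approach"], sub["psi_touch"])
        report["wilcoxon_by_duration_group"][grp] = {
            "statistic": float(stat),
            "p": float(p),
            "n": int(len(sub)),
            "mean_psi_change": float(sub["psi_change"].mean()),
        }

    corr = ok.loc[ok["correct"].astype(bool)]
    incorr = ok.loc[~ok["correct"].astype(bool)]
    if len(corr) >= 3 and len(incorr) >= 3:
        diff, p = two_sample_randomization_test(
            corr["psi_touch"].to_numpy(),
            incorr["psi_touch"].to_numpy(),
            n_iter=n_randomization,
            seed=rng,
        )
        report["psi_touch_correct_vs_incorrect"] = {
            "mean_correct": float(corr["psi_touch"].mean()),
            "mean_incorrect": float(incorr["psi_touch"].mean()),
            "difference": diff,
            "randomization_p": p,
        }
        t, tp = ttest_ind(
            corr["psi_change"], incorr["psi_change"], alternative="greater"
        )
        report["psi_change_correct_vs_incorrect_ttest"] = {
            "t": float(t),
            "one_tail_p": float(tp),
            "mean_correct": float(corr["psi_change"].mean()),
            "mean_incorrect": float(incorr["psi_change"].mean()),
        }
    else:
        report["skipped"].append("correct vs incorrect comparisons")

    report["psi_change_duration_group_ttests"] = {}
    groups = {g: sub["psi_change"] for g, sub in ok.groupby("duration_group")}
    for g1, g2 in (("fast", "intermediate"), ("intermediate", "slow"), ("fast", "slow")):
        if g1 in groups and g2 in groups and len(groups[g1]) >= 3 and len(groups[g2]) >= 3:
            t, tp = ttest_ind(groups[g1], groups[g2], alternative="greater")
            report["psi_change_duration_group_ttests"][f"{g1}_vs_{g2}"] = {
                "t": float(t),
                "one_tail_p": float(tp),
            }
        else:
            report["skipped"].append(f"t-test {g1} vs {g2}")
    return report
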