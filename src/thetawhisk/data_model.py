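"""Session container, HDF5 IO, behavioral episode segmentation, and the
behavioral-performance shuffle test.

A *session* bundles one continuous hippocampal LFP channel, one whisking
mean-angle trace, any number of sorted spike trains, and a per-trial event
table.  Episodes are derived from the event table:

- ``baseline``  — 2.5 to 3 s before first contact (fixed 500 ms),
- ``approach``  — the 500 ms ending at contact onset,
- ``touch``     — contact onset to final-contact offset (variable length),
- ``turn``      — contact offset to arrival at the reward spout,
- ``reward``    — the 500 ms starting at spout arrival.

Times are seconds (float64) relative to the session origin.  Windows are
half-open ``[start, end)`` for sample extraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: standard fixed episode length, close to the mean touch duration
STANDARD_EPISODE_S = 0.5
#: baseline interval relative to contact onset
BASELINE_OFFSET_S = (-3.0, -2.5)

EVENT_COLUMNS = [
    "trial_id",
    "contact_onset_s",
    "contact_offset_s",
    "spout_arrival_s",
    "reward_end_s",
    "texture_id",
    "choice_side",
    "correct",
]


class SchemaError(ValueError):
    """A session container is missing a required group/column."""


class ValidationError(ValueError):
    """Data violate a structural invariant (ordering, finiteness, ...)."""


@dataclass
class ContinuousSignal:
    """A uniformly sampled real-valued trace (LFP in µV or whisker angle in deg)."""

    samples: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("signal must be a non-empty 1-D array")
        if not np.isfinite(self.sample_rate_hz) or self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive and finite")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("signal samples must all be finite")

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.samples.size / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.sample_rate_hz


@dataclass
class TrialEvents:
    """Per-trial event timestamps and outcome labels."""

    trial_id: int
    contact_onset_s: float
    contact_offset_s: float
    spout_arrival_s: float
    reward_end_s: float
    texture_id: int = 0
    choice_side: str = ""
    correct: bool = True

    def __post_init__(self) -> None:
        if not (
            self.contact_onset_s
            < self.contact_offset_s
            <= self.spout_arrival_s
            <= self.reward_end_s
        ):
            raise ValidationError(
                f"trial {self.trial_id}: event order must satisfy "
                "contact_onset < contact_offset <= spout_arrival <= reward_end"
            )

    @property
    def touch_duration_s(self) -> float:
        return self.contact_offset_s - self.contact_onset_s


@dataclass(frozen=True)
class EpisodeWindow:
    """A labeled analysis window, half-open [start, end) for extraction."""

    label: str
    start_s: float
    end_s: float
    trial_id: int | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(f"window {self.label}: end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit."""

    unit_id: str
    spike_times_s: np.ndarray
    session_id: str = ""

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=np.float64)
        if self.spike_times_s.ndim != 1:
            raise ValidationError("spike times must be 1-D")
        if np.any(np.diff(self.spike_times_s) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times must be sorted")


@dataclass
class SessionBundle:
    """One recording (or simulated) session."""

    lfp: ContinuousSignal
    whisking: ContinuousSignal
    spikes: list[SpikeTrain] = field(default_factory=list)
    events: list[TrialEvents] = field(default_factory=list)
    truth: pd.DataFrame | None = None  # present iff synthetic

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(ev, c) for c in EVENT_COLUMNS} for ev in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def events_from_frame(df: pd.DataFrame) -> list[TrialEvents]:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"events table missing columns: {missing}")
    if df["trial_id"].duplicated().any():
        raise ValidationError("trial_ids must be unique")
    out = []
    for _, row in df.iterrows():
        out.append(
            TrialEvents(
                trial_id=int(row["trial_id"]),
                contact_onset_s=float(row["contact_onset_s"]),
                contact_offset_s=float(row["contact_offset_s"]),
                spout_arrival_s=float(row["spout_arrival_s"]),
                reward_end_s=float(row["reward_end_s"]),
                texture_id=int(row["texture_id"]),
                choice_side=str(row["choice_side"]),
                correct=bool(row["correct"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# HDF5 container IO
# ---------------------------------------------------------------------------

def _write_signal(group: h5py.Group, sig: ContinuousSignal) -> None:
    ds = group.create_dataset("samples", data=sig.samples)
    ds.attrs["sample_rate_hz"] = sig.sample_rate_hz
    ds.attrs["start_time_s"] = sig.start_time_s
    ds.attrs["units"] = sig.units
    ds.attrs["label"] = sig.label


def _read_signal(group: h5py.Group, name: str) -> ContinuousSignal:
    if "samples" not in group:
        raise SchemaError(f"group /{name} missing 'samples' dataset")
    ds = group["samples"]
    for attr in ("sample_rate_hz", "start_time_s"):
        if attr not in ds.attrs:
            raise SchemaError(f"/{name}/samples missing attribute '{attr}'")
    return ContinuousSignal(
        samples=ds[()],
        sample_rate_hz=float(ds.attrs["sample_rate_hz"]),
        start_time_s=float(ds.attrs["start_time_s"]),
        units=str(ds.attrs.get("units", "")),
        label=str(ds.attrs.get("label", name)),
    )


def write_session(bundle: SessionBundle, path) -> None:
    """Write a session to HDF5 (groups /lfp, /whisking, /spikes/<unit>, /events)."""
    with h5py.File(path, "w") as f:
        _write_signal(f.create_group("lfp"), bundle.lfp)
        _write_signal(f.create_group("whisking"), bundle.whisking)
        spikes = f.create_group("spikes")
        for st in bundle.spikes:
            spikes.create_dataset(st.unit_id, data=st.spike_times_s)
        ev = bundle.events_frame()
        g = f.create_group("events")
        for col in EVENT_COLUMNS:
            data = ev[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        if bundle.truth is not None:
            tg = f.create_group("truth")
            for col in bundle.truth.columns:
                tg.create_dataset(col, data=bundle.truth[col].to_numpy())


def read_session(path) -> SessionBundle:
    """Read a session container; inverse of :func:`write_session`."""
    with h5py.File(path, "r") as f:
        for name in ("lfp", "whisking", "events"):
            if name not in f:
                raise SchemaError(f"session container missing group /{name}")
        lfp = _read_signal(f["lfp"], "lfp")
        whisking = _read_signal(f["whisking"], "whisking")
        spikes = []
        if "spikes" in f:
            for unit_id in sorted(f["spikes"]):
                spikes.append(
                    SpikeTrain(unit_id=unit_id, spike_times_s=f["spikes"][unit_id][()])
                )
        g = f["events"]
        cols = {}
        for col in EVENT_COLUMNS:
            if col not in g:
                raise SchemaError(f"events table missing column '{col}'")
            data = g[col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        events = events_from_frame(pd.DataFrame(cols))
        truth = None
        if "truth" in f:
            truth = pd.DataFrame({c: f["truth"][c][()] for c in sorted(f["truth"])})
    return SessionBundle(lfp=lfp, whisking=whisking, spikes=spikes, events=events, truth=truth)


# ---------------------------------------------------------------------------
# Episode segmentation and window extraction
# ---------------------------------------------------------------------------

def segment_episodes(
    events: Sequence[TrialEvents],
    analysis_len_s: float = STANDARD_EPISODE_S,
    session_start_s: float = 0.0,
) -> list[EpisodeWindow]:
    """Derive the five task episodes of each trial from its event timestamps.

    Per trial: baseline ``[onset-3, onset-2.5]``, approach ``[onset-0.5, onset)``,
    touch ``[onset, offset]``, turn ``(offset, arrival]``, reward
    ``[arrival, arrival+0.5]``.  Trials whose baseline would precede the session
    start lose only the baseline window (with a logged warning).  Overlapping
    trials are rejected.
    """
    ordered = sorted(events, key=lambda e: e.contact_onset_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.contact_onset_s + BASELINE_OFFSET_S[0] < prev.reward_end_s:
            raise ValidationError(
                f"trials {prev.trial_id} and {nxt.trial_id} overlap "
                "(baseline of the later trial begins before the earlier trial ends)"
            )
    windows: list[EpisodeWindow] = []
    for ev in ordered:
        onset = ev.contact_onset_s
        if onset + BASELINE_OFFSET_S[0] >= session_start_s:
            windows.append(
                EpisodeWindow(
                    "baseline",
                    onset + BASELINE_OFFSET_S[0],
                    onset + BASELINE_OFFSET_S[1],
                    ev.trial_id,
                )
            )
        else:
            logger.warning(
                "trial %d too close to session start; baseline omitted", ev.trial_id
            )
        windows.append(
            EpisodeWindow("approach", onset - analysis_len_s, onset, ev.trial_id)
        )
        windows.append(EpisodeWindow("touch", onset, ev.contact_offset_s, ev.trial_id))
        windows.append(
            EpisodeWindow("turn", ev.contact_offset_s, ev.spout_arrival_s, ev.trial_id)
        )
        windows.append(
            EpisodeWindow(
                "reward",
                ev.spout_arrival_s,
                ev.spout_arrival_s + analysis_len_s,
                ev.trial_id,
            )
        )
    return windows


def waiting_windows(
    events: Sequence[TrialEvents],
    session_start_s: float,
    session_end_s: float,
    window_len_s: float = STANDARD_EPISODE_S,
    guard_s: float = 1.0,
) -> list[EpisodeWindow]:
    """Tile 500 ms 'waiting' windows over inter-trial intervals.

    The task leaves the waiting epoch's exact bounds open; here it is any time at
    least ``guard_s`` away from the surrounding trials' bridge events (taken as
    the span from 3 s pre-contact to reward end).
    """
    ordered = sorted(events, key=lambda e: e.contact_onset_s)
    busy = [
        (ev.contact_onset_s + BASELINE_OFFSET_S[0], ev.reward_end_s) for ev in ordered
    ]
    gaps = []
    cursor = session_start_s
    for lo, hi in busy:
        if lo - guard_s > cursor + guard_s:
            gaps.append((cursor + guard_s, lo - guard_s))
        cursor = max(cursor, hi)
    if session_end_s - guard_s > cursor + guard_s:
        gaps.append((cursor + guard_s, session_end_s - guard_s))
    windows = []
    for lo, hi in gaps:
        n = int(np.floor((hi - lo) / window_len_s))
        for k in range(n):
            windows.append(
                EpisodeWindow("waiting", lo + k * window_len_s, lo + (k + 1) * window_len_s)
            )
    return windows


def extract_window(signal: ContinuousSignal, window: EpisodeWindow) -> np.ndarray:
    """Samples of ``signal`` in ``[start, end)`` at the native rate.

    Length is ``round(duration * rate)``; raises if the window leaves the
    signal's extent.
    """
    fs = signal.sample_rate_hz
    i0 = int(round((window.start_s - signal.start_time_s) * fs))
    n = int(round(window.duration_s * fs))
    if i0 < 0 or i0 + n > signal.samples.size:
        raise ValueError(
            f"window [{window.start_s}, {window.end_s}) outside signal extent "
            f"[{signal.start_time_s}, {signal.end_time_s})"
        )
    return signal.samples[i0 : i0 + n]


# ---------------------------------------------------------------------------
# Behavioral performance shuffle test
# ---------------------------------------------------------------------------

def percent_correct(
    texture_ids: np.ndarray, choices: np.ndarray, rewarded_side: Mapping
) -> float:
    correct_sides = np.array([rewarded_side[t] for t in texture_ids])
    return 100.0 * float(np.mean(np.asarray(choices) == correct_sides))


def performance_randomization_test(
    texture_ids,
    choices,
    rewarded_side: Mapping,
    n_shuffles: int = 500,
    seed: int | np.random.Generator | None = None,
):
    """Shuffle texture labels across trials to test performance against chance.

    ``rewarded_side`` maps each texture id to the rewarded choice side.  Returns
    ``(observed percent correct, p)`` with
    ``p = (1 + #{shuffled >= observed}) / (n_shuffles + 1)``.
    """
    texture_ids = np.asarray(texture_ids)
    choices = np.asarray(choices)
    if texture_ids.shape != choices.shape:
        raise ValueError("texture_ids and choices must have equal length")
    if np.unique(texture_ids).size < 2:
        raise ValueError("shuffle test needs at least two distinct textures")
    rng = np.random.default_rng(seed)
    observed = percent_correct(texture_ids, choices, rewarded_side)
    count = 0
    for _ in range(n_shuffles):
        shuffled = rng.permutation(texture_ids)
        if percent_correct(shuffled, choices, rewarded_side) >= observed:
            count += 1
    p = (1 + count) / (n_shuffles + 1)
    return observed, p
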