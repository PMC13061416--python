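"""Larval sleep-bout calling, sleep/locomotion metrics, the optogenetic
light-response normalization, and the deprivation schedule with rebound.

Sleep is defined as a maximal inactive run of at least ``min_frames``
consecutive frames (12 at the 0.87 fps default, ~13.8 s). Bout intervals
are half-open ``[start, end)`` in frames; durations convert through the
frame rate. Bouts truncated by the recording edges count if they meet the
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .activity import BehaviorTrace, CentroidTrack
from .errors import InvalidParameterError
from .synthetic import inactive_runs

DEFAULT_MIN_SLEEP_FRAMES = 12


@dataclass(frozen=True)
class SleepBout:
    """One sleep bout as a half-open frame interval."""

    start_frame: int
    end_frame: int
    fps: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def interval_s(self) -> tuple[float, float]:
        return (self.start_frame / self.fps, self.end_frame / self.fps)


@dataclass
class SleepMetrics:
    """Sleep architecture summary over one analysis window (seconds).

    ``sleep_latency_s`` is NaN (undefined) when no bout intersects the
    window; ``total_sleep_s + total_wake_s`` equals the window length
    exactly.
    """

    total_sleep_s: float
    bout_count: int
    mean_bout_s: float
    sleep_latency_s: float
    total_wake_s: float
    window: tuple[float, float]


@dataclass
class StimulusSchedule:
    """LED stimulation schedule: half-open ON intervals in seconds."""

    on_intervals: list[tuple[float, float]]
    baseline_s: float
    on_s: float
    off_s: float

    @property
    def total_on_s(self) -> float:
        return sum(e - s for s, e in self.on_intervals)


def call_sleep_bouts(trace: BehaviorTrace,
                     min_frames: int = DEFAULT_MIN_SLEEP_FRAMES) -> list[SleepBout]:
    """Return the maximal inactive runs of length >= ``min_frames``."""
    if min_frames < 1:
        raise InvalidParameterError("min_frames must be >= 1")
    return [SleepBout(s, e, trace.fps)
            for s, e in inactive_runs(trace.states) if e - s >= min_frames]


def sleep_metrics(bouts: list[SleepBout], trace: BehaviorTrace,
                  window: tuple[float, float] | None = None) -> SleepMetrics:
    """Summarize sleep architecture over an analysis window.

    Total sleep is the summed intersection of bout intervals (in seconds)
    with the window; wake is the complement. Latency is the start of the
    first intersecting bout relative to the window start, NaN if none.
    """
    recording_s = len(trace) / trace.fps
    if window is None:
        window = (0.0, recording_s)
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= recording_s + 1e-9):
        raise InvalidParameterError(
            f"window {window} outside recording [0, {recording_s:.3f}]")
    total_sleep = 0.0
    durations = []
    latency = np.nan
    for bout in bouts:
        bs, be = bout.interval_s
        inter = min(be, t1) - max(bs, t0)
        if inter > 0:
            total_sleep += inter
            durations.append(inter)
            if np.isnan(latency):
                latency = max(bs, t0) - t0
    return SleepMetrics(
        total_sleep_s=total_sleep,
        bout_count=len(durations),
        mean_bout_s=float(np.mean(durations)) if durations else np.nan,
        sleep_latency_s=latency,
        total_wake_s=(t1 - t0) - total_sleep,
        window=(t0, t1),
    )


def sleep_seconds_in_interval(bouts: list[SleepBout],
                              interval_s: tuple[float, float]) -> float:
    """Summed sleep (seconds) intersecting one half-open second interval."""
    t0, t1 = interval_s
    return sum(max(0.0, min(b.interval_s[1], t1) - max(b.interval_s[0], t0))
               for b in bouts)


def locomotion_speed(track: CentroidTrack, bouts: list[SleepBout],
                     fps: float) -> float:
    """Wake-gated locomotion speed: travel distance / wake time.

    Only displacements between consecutive frames that are both classified
    wake and both validly tracked enter the numerator; the matching frame
    intervals form the denominator, so inserted sleep (or tracking
    dropouts) are excluded from both terms. Returns NaN with a warning when
    no wake time remains.
    """
    T = len(track)
    asleep = np.zeros(T, dtype=bool)
    for b in bouts:
        asleep[b.start_frame:b.end_frame] = True
    wake_valid = (~asleep) & track.valid
    pair_ok = wake_valid[1:] & wake_valid[:-1]
    if not pair_ok.any():
        warnings.warn("no valid wake time; locomotion speed undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    deltas = np.diff(track.positions, axis=0)
    dist = float(np.linalg.norm(deltas[pair_ok], axis=1).sum())
    wake_time_s = float(pair_ok.sum()) / fps
    return dist / wake_time_s


def light_response_index(sleep_on_s: float, sleep_off_s: float) -> float:
    """Sleep during the light-ON hour normalized to the light-OFF hour."""
    if sleep_on_s < 0 or sleep_off_s < 0:
        raise InvalidParameterError("sleep durations must be >= 0")
    if sleep_off_s == 0:
        warnings.warn("no baseline (light-OFF) sleep; light response undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return sleep_on_s / sleep_off_s


def deprivation_schedule(baseline_s: float = 3600.0, on_s: float = 90.0,
                         off_s: float = 30.0,
                         session_s: float = 3600.0) -> StimulusSchedule:
    """Build the sleep-deprivation LED schedule.

    One baseline hour without illumination, then repeated cycles of LED ON
    for ``on_s`` and OFF for ``off_s`` until the end of the deprivation
    session; a final partial ON interval is truncated at session end.
    """
    for name, v in (("baseline_s", baseline_s), ("on_s", on_s),
                    ("off_s", off_s), ("session_s", session_s)):
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0")
    if session_s > 0 and on_s + off_s == 0:
        raise InvalidParameterError("on_s + off_s must be positive for a session")
    intervals: list[tuple[float, float]] = []
    end = baseline_s + session_s
    t = baseline_s
    while t < end and on_s > 0:
        intervals.append((t, min(t + on_s, end)))
        t += on_s + off_s
    return StimulusSchedule(intervals, baseline_s, on_s, off_s)


def rebound_index(sleep_pre_s: float, sleep_post_s: float) -> float:
    """Post- over pre-deprivation sleep; values > 1 indicate a rebound."""
    if sleep_pre_s < 0 or sleep_post_s < 0:
        raise InvalidParameterError("sleep durations must be >= 0")
    if sleep_pre_s == 0:
        warnings.warn("no pre-deprivation sleep; rebound index undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return sleep_post_s / sleep_pre_s


def metrics_record(animal_id: str, metrics: SleepMetrics,
                   wake_speed: float | None = None) -> dict:
    """Flatten one animal's metrics into the per-animal CSV row schema."""
    rec = {
        "animal_id": animal_id,
        "window_s": metrics.window[1] - metrics.window[0],
        "total_sleep_s": metrics.total_sleep_s,
        "bout_count": metrics.bout_count,
        "mean_bout_s": metrics.mean_bout_s,
        "latency_s": metrics.sleep_latency_s,
    }
    if wake_speed is not None:
        rec["wake_speed_mm_s"] = wake_speed
    return rec
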