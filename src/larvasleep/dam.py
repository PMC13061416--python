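"""Adult sleep scoring from DAM beam-crossing series.

Sleep in adult flies is scored with the conventional immobility criterion:
a maximal run of at least five consecutive one-minute bins with zero beam
crossings is a sleep bout. Excluded (error-status) bins break immobility
runs rather than being imputed as zeros — immobility is never fabricated.
Bout minutes are apportioned to the light and dark phase by clock time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, OrderingError
from .io import DAMSeries

DEFAULT_MIN_GAP_MIN = 5
MINUTES_PER_DAY = 24 * 60


@dataclass
class AdultSleepResult:
    """Scored sleep for one DAM channel.

    ``bouts`` are half-open minute intervals since recording start. Totals
    are summed over the analyzed span; ``day_sleep_min + night_sleep_min``
    equals ``total_sleep_min`` exactly. ``daily`` breaks a multi-day
    recording into full 24-h windows aligned to the recording start.
    """

    bouts: list[tuple[int, int]]
    total_sleep_min: float
    day_sleep_min: float
    night_sleep_min: float
    bout_count: int
    mean_bout_min: float
    start_minute_of_day: int
    lights_on_min: int
    lights_off_min: int
    daily: list[dict] = field(default_factory=list)


def _zero_runs(zero_ok: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], zero_ok, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def _minute_is_day(minute_of_day: np.ndarray, lights_on: int,
                   lights_off: int) -> np.ndarray:
    if lights_on < lights_off:
        return (minute_of_day >= lights_on) & (minute_of_day < lights_off)
    # lights span midnight
    return (minute_of_day >= lights_on) | (minute_of_day < lights_off)


def ld_phase_split(bouts: list[tuple[int, int]], start_minute_of_day: int,
                   lights_on_min: int = 9 * 60,
                   lights_off_min: int = 21 * 60) -> tuple[float, float]:
    """Apportion bout minutes to the light (day) and dark (night) phase.

    Each bout minute is labeled by its clock time; a bout crossing the
    transition therefore splits in exact minute proportion.
    """
    if lights_on_min == lights_off_min:
        raise InvalidParameterError("lights_on and lights_off must differ")
    day = night = 0
    for s, e in bouts:
        minutes = (start_minute_of_day + np.arange(s, e)) % MINUTES_PER_DAY
        is_day = _minute_is_day(minutes, lights_on_min, lights_off_min)
        day += int(is_day.sum())
        night += int((~is_day).sum())
    return float(day), float(night)


def score_adult_sleep(series: DAMSeries, min_gap_min: int = DEFAULT_MIN_GAP_MIN,
                      channel: int | None = None) -> AdultSleepResult:
    """Score sleep bouts for one channel of a DAM series.

    ``channel`` is a channel id from ``series.channel_ids`` (defaults to the
    first). Bouts are maximal runs of >= ``min_gap_min`` zero-count valid
    bins.
    """
    if min_gap_min < 1:
        raise InvalidParameterError("min_gap_min must be >= 1")
    if channel is None:
        channel = series.channel_ids[0]
    counts = series.channel(channel)
    excluded = series.excluded if series.excluded is not None else np.zeros(
        len(counts), dtype=bool)
    zero_ok = (counts == 0) & ~excluded
    bouts = _zero_runs(zero_ok, min_gap_min)

    day, night = ld_phase_split(bouts, series.start_minute_of_day,
                                series.lights_on_min, series.lights_off_min)
    durations = [e - s for s, e in bouts]
    n_days = series.n_minutes // MINUTES_PER_DAY
    daily = []
    for d in range(n_days):
        w0, w1 = d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY
        day_bouts = [(max(s, w0), min(e, w1)) for s, e in bouts
                     if min(e, w1) > max(s, w0)]
        dd, dn = ld_phase_split(day_bouts, series.start_minute_of_day,
                                series.lights_on_min, series.lights_off_min)
        daily.append({"day": d, "total_sleep_min": float(dd + dn),
                      "day_sleep_min": dd, "night_sleep_min": dn,
                      "bout_count": len(day_bouts)})
    return AdultSleepResult(
        bouts=bouts,
        total_sleep_min=float(sum(durations)),
        day_sleep_min=day,
        night_sleep_min=night,
        bout_count=len(bouts),
        mean_bout_min=float(np.mean(durations)) if durations else np.nan,
        start_minute_of_day=series.start_minute_of_day,
        lights_on_min=series.lights_on_min,
        lights_off_min=series.lights_off_min,
        daily=daily,
    )


def validate_uniform_bins(minute_offsets: np.ndarray) -> None:
    """Raise when minute offsets are not consecutive 1-min bins."""
    offs = np.asarray(minute_offsets)
    if offs.size and not np.all(np.diff(offs) == 1):
        raise OrderingError("DAM series has gaps or non-uniform 1-min bins")


def adult_sleep_record(channel: int, result: AdultSleepResult) -> dict:
    """Flatten one fly's scored sleep into the per-fly CSV row schema."""
    return {
        "channel": channel,
        "total_sleep_min": result.total_sleep_min,
        "day_sleep_min": result.day_sleep_min,
        "night_sleep_min": result.night_sleep_min,
        "bout_count": result.bout_count,
        "mean_bout_min": result.mean_bout_min,
    }
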