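"""Frame-differencing activity classification and centroid tracking.

A larva is annotated per frame as ``active`` or ``inactive`` from the number
of in-well pixels whose intensity changed between consecutive frames beyond
a per-pixel noise floor. Counting changed pixels (rather than summing
absolute differences) makes the score robust to static illumination
gradients. The centroid tracker supplies the travel distances behind the
wake-gated locomotion speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (DegenerateInputError, EmptyWellError, InvalidParameterError)
from .io import FrameStack, WellBox

#: Default per-pixel intensity-change floor (8-bit units) below which a
#: pixel difference is attributed to sensor noise.
DEFAULT_NOISE_FLOOR = 10.0


@dataclass
class ActivityScoreSeries:
    """Per-frame pixel-change scores for one well.

    ``scores[t]`` counts the pixels of frame ``t`` whose absolute intensity
    difference from frame ``t - 1`` exceeds the noise floor. Frame 0 has no
    predecessor and copies frame 1's score so that the recording does not
    start with a spurious state.
    """

    scores: np.ndarray
    fps: float
    noise_floor: float = DEFAULT_NOISE_FLOOR
    threshold: float | None = None
    well_id: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if np.any(self.scores < 0):
            raise InvalidParameterError("pixel-change scores must be non-negative")


@dataclass
class BehaviorTrace:
    """Per-frame binary activity labels; ``states[t]`` is True when active."""

    states: np.ndarray
    fps: float
    well_id: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.fps <= 0:
            raise InvalidParameterError("fps must be positive")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class CentroidTrack:
    """Per-frame larval centroid positions.

    ``positions[t]`` is (x, y) in mm (or px when no optical calibration is
    available; see ``units``). ``valid[t]`` is False when no foreground blob
    was found at frame ``t``; the position is then carried forward from the
    last valid frame.
    """

    positions: np.ndarray
    valid: np.ndarray
    units: str = "mm"
    well_id: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.positions)


def _crop(stack: FrameStack, well: WellBox | None) -> np.ndarray:
    T, H, W = stack.shape
    if well is None:
        return stack.frames
    if not (0 <= well.top < well.bottom <= H and 0 <= well.left < well.right <= W):
        raise InvalidParameterError(f"well box {well} outside {H}x{W} frame")
    return stack.frames[:, well.top:well.bottom, well.left:well.right]


def pixel_change_scores(stack: FrameStack, well: WellBox | None = None,
                        noise_floor: float = DEFAULT_NOISE_FLOOR,
                        well_id: str | None = None) -> ActivityScoreSeries:
    """Count, per frame, the in-well pixels changed beyond the noise floor."""
    frames = _crop(stack, well)
    if frames.shape[0] < 2:
        raise InvalidParameterError("need at least 2 frames for differencing")
    diff = np.abs(frames[1:].astype(np.int16) - frames[:-1].astype(np.int16))
    changed = (diff > noise_floor).sum(axis=(1, 2))
    scores = np.empty(frames.shape[0], dtype=np.int64)
    scores[1:] = changed
    scores[0] = scores[1]
    return ActivityScoreSeries(scores, fps=stack.fps, noise_floor=noise_floor,
                               well_id=well_id)


def calibrate_activity_threshold(scores: ActivityScoreSeries | np.ndarray,
                                 labels: np.ndarray | None = None) -> float:
    """Choose the score cutoff separating quiescent from active frames.

    Without labels, an Otsu two-class split of the score histogram is used.
    With per-frame truth labels (True = active), the threshold maximizing
    frame-level accuracy under the strict ``score > threshold`` rule is
    returned (smallest such threshold on ties). Deterministic for fixed
    input.
    """
    s = scores.scores if isinstance(scores, ActivityScoreSeries) else np.asarray(scores)
    s = s.astype(np.float64)
    if s.size < 100:
        raise InvalidParameterError("need at least 100 frames to calibrate")
    if np.ptp(s) == 0:
        raise DegenerateInputError("all scores identical; cannot calibrate")
    if labels is None:
        # Otsu two-class split computed exactly on the empirical score
        # values (no histogram binning): maximize the between-class
        # variance over every cut between consecutive distinct scores,
        # then place the threshold at the midpoint of the chosen gap.
        srt = np.sort(s)
        cuts = np.flatnonzero(np.diff(srt) > 0) + 1  # first index of upper class
        n = srt.size
        csum = np.concatenate([[0.0], np.cumsum(srt)])
        w1 = cuts / n
        m1 = csum[cuts] / cuts
        m2 = (csum[-1] - csum[cuts]) / (n - cuts)
        between = w1 * (1 - w1) * (m1 - m2) ** 2
        k = cuts[int(np.argmax(between))]
        return max(0.0, float(srt[k - 1] + srt[k]) / 2.0)
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != s.shape:
        raise InvalidParameterError("labels must align with scores")
    if labels.all() or (~labels).all():
        raise InvalidParameterError("labeled calibration needs both classes present")
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    lab_sorted = labels[order].astype(np.int64)
    cum_active = np.concatenate([[0], np.cumsum(lab_sorted)])
    n = s.size
    total_active = cum_active[-1]
    # cutting after index k predicts the first k frames (score <= candidate)
    # inactive; correct = inactive among first k + active among the rest
    uniq_last = np.flatnonzero(np.diff(s_sorted, append=np.inf))  # last index of each value
    ks = uniq_last + 1
    if s_sorted[0] > 0:
        # "all frames active" is only reachable when a threshold >= 0 can
        # sit strictly below every score
        ks = np.concatenate([[0], ks])
    correct = (ks - cum_active[ks]) + (total_active - cum_active[ks])
    best = int(np.argmax(correct))
    k = ks[best]
    if k == 0:
        return float(s_sorted[0]) / 2.0
    return float(s_sorted[k - 1])


def classify_activity(scores: ActivityScoreSeries, threshold: float) -> BehaviorTrace:
    """Label frames active iff ``score > threshold`` (ties break inactive)."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    return BehaviorTrace(scores.scores > threshold, fps=scores.fps,
                         well_id=scores.well_id)


def median_filter_states(trace: BehaviorTrace, size: int = 3) -> BehaviorTrace:
    """Optional temporal median smoothing of activity labels (off by default
    in the pipeline; the bout-length criterion already denoises)."""
    if size % 2 != 1 or size < 1:
        raise InvalidParameterError("filter size must be an odd positive integer")
    smoothed = ndimage.median_filter(trace.states.astype(np.int8), size=size,
                                     mode="nearest") > 0
    return BehaviorTrace(smoothed, fps=trace.fps, well_id=trace.well_id)


def _sliding_median_background(frames: np.ndarray, window: int = 101,
                               stride: int = 5) -> np.ndarray:
    """Per-pixel temporal median over a sliding window.

    Windows are subsampled every ``stride`` frames; the larva occupies any
    given pixel for a minority of wake frames, so the subsampled median
    still converges to the static background.
    """
    T = frames.shape[0]
    half = window // 2
    if T <= window:
        bg = np.median(frames[::max(1, T // 21) or 1], axis=0)
        return np.broadcast_to(bg, frames.shape)
    out = np.empty_like(frames, dtype=np.float64)
    for t in range(T):
        lo = max(0, t - half)
        hi = min(T, t + half + 1)
        out[t] = np.median(frames[lo:hi:stride], axis=0)
    return out


def track_centroids(stack: FrameStack, well: WellBox | None = None,
                    noise_floor: float = DEFAULT_NOISE_FLOOR,
                    background_window: int = 101,
                    well_id: str | None = None) -> CentroidTrack:
    """Track the larval centroid within one well.

    The background is modelled as a per-pixel temporal median; the
    foreground blob is the connected component deviating most strongly from
    it, and its intensity-weighted centroid is reported per frame. A larva
    that never moves leaves no trace in the difference image, so frames
    without background deviation fall back to dark-object segmentation
    against the background level. Frames with no foreground at all are
    flagged invalid and carry the last valid position forward.
    """
    frames = _crop(stack, well).astype(np.float64)
    T = frames.shape[0]
    bg = _sliding_median_background(frames, window=background_window)
    offset_rc = (well.top, well.left) if well is not None else (0, 0)
    scale = stack.pixel_size_mm if stack.pixel_size_mm is not None else 1.0
    units = "mm" if stack.pixel_size_mm is not None else "px"

    positions = np.full((T, 2), np.nan)
    valid = np.zeros(T, dtype=bool)
    dark_cut = 0.5 * float(np.median(bg))
    for t in range(T):
        # The larva images darker than the substrate. The signed difference
        # from the median background ignores the bright "ghost" a
        # long-parked larva leaves after moving away; the dark-object cue
        # recovers a larva parked long enough to be absorbed into the
        # median itself. Union of both cues, brighter-deviation weighting.
        dev = bg[t] - frames[t]
        dark = dark_cut - frames[t]
        mask = (dev > noise_floor) | (dark > 0)
        # prefer the dark-object weight where defined: it is uniform over
        # the body, while the background deviation can cover only the part
        # of a parked larva not yet absorbed into the median (biasing the
        # centroid toward it)
        weights = np.where(dark > 0, dark, np.maximum(dev, 0.0))
        if mask.any():
            lbl, n = ndimage.label(mask)
            if n > 1:
                sums = ndimage.sum_labels(weights * mask, lbl, index=np.arange(1, n + 1))
                mask = lbl == (1 + int(np.argmax(sums)))
            w = np.where(mask, weights, 0.0)
            tot = w.sum()
            rr, cc = np.nonzero(mask)
            r = float((w[rr, cc] * rr).sum() / tot)
            c = float((w[rr, cc] * cc).sum() / tot)
            positions[t] = ((c + offset_rc[1]) * scale, (r + offset_rc[0]) * scale)
            valid[t] = True
    if not valid.any():
        raise EmptyWellError("no foreground found in any frame of this well")
    # carry last valid position forward; frames before the first valid frame
    # take the first valid position (still flagged invalid)
    first = int(np.argmax(valid))
    positions[:first] = positions[first]
    for t in range(first + 1, T):
        if not valid[t]:
            positions[t] = positions[t - 1]
    return CentroidTrack(positions, valid, units=units, well_id=well_id)
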