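"""Ground-truthed synthetic inputs for every pipeline stage.

The generators emulate the study conditions of a larval sleep rig: a single
second-instar larva per well, imaged at 0.87 fps under infrared
illumination; alternating wake/quiescence bouts; DAM beam-crossing series
following a programmed sleep schedule; two-channel translocation-reporter
cell images with a controllable nuclear signal fraction; and dye-fed larvae
with a stained gut region of known area fraction.

All randomness flows through one explicitly passed integer seed; there is
no global random state, and identical arguments with an identical seed give
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .activity import BehaviorTrace
from .errors import InvalidParameterError
from .io import DAMSeries, FrameStack, trace_frame_table

# ---------------------------------------------------------------------------
# Ground truth and parameter containers
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Truth record attached to every synthetic artifact.

    ``state_sequence`` holds the per-frame activity labels (True = active);
    ``true_bouts`` are the maximal inactive runs as half-open frame
    intervals; ``true_centroids`` is the rendered (x_mm, y_mm) path (filled
    in by the video renderer; centroids are constant within inactive runs).
    """

    state_sequence: np.ndarray
    true_bouts: list[tuple[int, int]]
    true_centroids: np.ndarray | None = None
    true_nuclear_fraction: float | None = None
    true_stain_fraction: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=bool)


@dataclass
class MotionParams:
    """Larval motion and imaging parameters for the video renderer.

    Defaults approximate a second-instar larva on the described rig:
    0.87 fps acquisition, ~0.4 mm/s crawl speed during wake, a ~2.5 mm body
    imaged at 0.1 mm/px, mild sensor noise, and a static linear illumination
    gradient.
    """

    fps: float = 0.87
    crawl_speed_mean: float = 0.4      # mm/s during wake
    peristalsis_amplitude: float = 2.0  # px of body-length oscillation
    body_length: float = 25.0           # px
    noise_sd: float = 2.0               # 8-bit intensity units
    illum_gradient: float = 0.1         # fractional left-right gradient
    pixel_size_mm: float = 0.1          # mm per px
    background_intensity: float = 200.0
    larva_intensity: float = 60.0
    heading_sd: float = 0.5             # rad per wake frame (correlated walk)
    speed_jitter: float = 0.1           # fractional per-frame step jitter
    micro_movement_px: float = 0.0      # optional sub-threshold sleep jitter

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidParameterError("fps must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.crawl_speed_mean < 0:
            raise InvalidParameterError("crawl_speed_mean must be >= 0")


def inactive_runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of inactive frames as half-open (start, end) intervals."""
    inact = ~np.asarray(states, dtype=bool)
    padded = np.concatenate([[False], inact, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# Behavioral state sequences
# ---------------------------------------------------------------------------


def simulate_behavior_trace(fps: float, duration_s: float, mean_wake_s: float,
                            mean_sleep_s: float, seed: int
                            ) -> tuple[BehaviorTrace, GroundTruth]:
    """Simulate an alternating wake/quiescence state sequence.

    Bout lengths in frames are geometric (memoryless, support >= 1 frame)
    with means matching the requested durations. ``mean_sleep_s = 0`` yields
    an all-active trace and ``mean_wake_s = 0`` an all-inactive one. The
    first bout is a wake bout (recordings start when the larva is placed).
    """
    if fps <= 0 or duration_s <= 0:
        raise InvalidParameterError("fps and duration_s must be positive")
    if mean_wake_s < 0 or mean_sleep_s < 0:
        raise InvalidParameterError("mean bout durations must be >= 0")
    if mean_wake_s == 0 and mean_sleep_s == 0:
        raise InvalidParameterError("wake and sleep means cannot both be zero")
    n_frames = max(1, int(round(duration_s * fps)))
    rng = np.random.default_rng(seed)
    if mean_sleep_s == 0:
        states = np.ones(n_frames, dtype=bool)
    elif mean_wake_s == 0:
        states = np.zeros(n_frames, dtype=bool)
    else:
        p_wake = min(1.0, 1.0 / max(1.0, mean_wake_s * fps))
        p_sleep = min(1.0, 1.0 / max(1.0, mean_sleep_s * fps))
        chunks: list[np.ndarray] = []
        total = 0
        awake = True
        while total < n_frames:
            length = int(rng.geometric(p_wake if awake else p_sleep))
            chunks.append(np.full(length, awake))
            total += length
            awake = not awake
        states = np.concatenate(chunks)[:n_frames]
    truth = GroundTruth(state_sequence=states, true_bouts=inactive_runs(states),
                        seed=seed)
    return BehaviorTrace(states, fps=fps), truth


# ---------------------------------------------------------------------------
# Larva video rendering
# ---------------------------------------------------------------------------


def _render_ellipse(canvas: np.ndarray, center_rc: tuple[float, float],
                    semi_major: float, semi_minor: float, heading: float,
                    intensity: float, grids: tuple[np.ndarray, np.ndarray]) -> None:
    yy, xx = grids
    dy = yy - center_rc[0]
    dx = xx - center_rc[1]
    u = dx * np.cos(heading) + dy * np.sin(heading)
    v = -dx * np.sin(heading) + dy * np.cos(heading)
    inside = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    canvas[inside] = intensity


def render_larva_video(truth: GroundTruth, motion: MotionParams,
                       well_size_px: int = 80, seed: int = 0) -> FrameStack:
    """Render one well's video from a behavioral state sequence.

    The larva is an ellipse whose length oscillates sinusoidally during wake
    (a peristalsis proxy) and whose centroid follows a correlated random
    walk with mean per-frame displacement ``crawl_speed_mean / fps``;
    during quiescent frames the body is frozen and only sensor noise
    varies. The rendered centroid path is written back into
    ``truth.true_centroids`` in mm.
    """
    states = truth.state_sequence
    T = len(states)
    L = motion.body_length
    amp = motion.peristalsis_amplitude
    margin = L / 2 + amp + 2.0
    if well_size_px <= 2 * margin:
        raise InvalidParameterError(
            f"well_size_px={well_size_px} too small for body_length={L}")
    rng = np.random.default_rng(seed)
    H = W = int(well_size_px)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    gradient = 1.0 + motion.illum_gradient * (xx / max(1, W - 1) - 0.5)
    background = motion.background_intensity * gradient

    semi_minor0 = L / 6.0
    step_px = motion.crawl_speed_mean / motion.fps / motion.pixel_size_mm
    pos = np.array([H / 2.0, W / 2.0])  # (row, col)
    heading = float(rng.uniform(0, 2 * np.pi))
    phase = 0.0

    frames = np.empty((T, H, W), dtype=np.uint8)
    centroids_px = np.empty((T, 2))
    lo, hi = margin, well_size_px - 1 - margin
    for t in range(T):
        if t > 0 and states[t]:
            heading += float(rng.normal(0.0, motion.heading_sd))
            step = step_px * max(0.0, float(rng.normal(1.0, motion.speed_jitter)))
            proposal = pos + step * np.array([np.sin(heading), np.cos(heading)])
            for axis in (0, 1):
                if proposal[axis] < lo:
                    proposal[axis] = 2 * lo - proposal[axis]
                    heading = -heading if axis == 0 else np.pi - heading
                elif proposal[axis] > hi:
                    proposal[axis] = 2 * hi - proposal[axis]
                    heading = -heading if axis == 0 else np.pi - heading
            pos = proposal
            phase += 2 * np.pi / 3.0
        elif t > 0 and motion.micro_movement_px > 0:
            pos = np.clip(pos + rng.uniform(-motion.micro_movement_px,
                                            motion.micro_movement_px, size=2),
                          lo, hi)
        length = L + (amp * np.sin(phase) if states[t] else 0.0)
        semi_major = length / 2.0
        semi_minor = (L / 2.0) * semi_minor0 / semi_major  # area-conserving
        canvas = background.copy()
        _render_ellipse(canvas, (pos[0], pos[1]), semi_major, semi_minor,
                        heading, motion.larva_intensity, (yy, xx))
        if motion.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, motion.noise_sd, size=(H, W))
        frames[t] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
        centroids_px[t] = pos
    truth.true_centroids = np.column_stack([
        centroids_px[:, 1] * motion.pixel_size_mm,   # x from columns
        centroids_px[:, 0] * motion.pixel_size_mm,   # y from rows
    ])
    return FrameStack(frames, fps=motion.fps, pixel_size_mm=motion.pixel_size_mm)


# ---------------------------------------------------------------------------
# DAM count series
# ---------------------------------------------------------------------------


def simulate_dam_series(sleep_schedule: list[tuple[int, int]],
                        mean_counts_awake: float, n_minutes: int,
                        seed: int = 0) -> DAMSeries:
    """Simulate a single-channel DAM count series under a sleep schedule.

    Minutes inside the half-open schedule intervals count 0 crossings;
    minutes outside draw from a zero-truncated Poisson with the stated
    mean, so wake bins are never silent.
    """
    if n_minutes <= 0:
        raise InvalidParameterError("n_minutes must be positive")
    if mean_counts_awake <= 0:
        raise InvalidParameterError("mean_counts_awake must be positive")
    occupied = np.zeros(n_minutes, dtype=bool)
    for start, end in sorted(sleep_schedule):
        if not (0 <= start < end <= n_minutes):
            raise InvalidParameterError(
                f"schedule interval ({start}, {end}) outside [0, {n_minutes})")
        if occupied[start:end].any():
            raise InvalidParameterError("schedule intervals overlap")
        occupied[start:end] = True
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_minutes, dtype=np.int64)
    wake = ~occupied
    n_wake = int(wake.sum())
    if n_wake:
        draws = rng.poisson(mean_counts_awake, size=n_wake)
        while (zero := draws == 0).any():
            draws[zero] = rng.poisson(mean_counts_awake, size=int(zero.sum()))
        counts[wake] = draws
    return DAMSeries(counts=counts.reshape(-1, 1), channel_ids=[1])


# ---------------------------------------------------------------------------
# Translocation-reporter cell images
# ---------------------------------------------------------------------------


@dataclass
class CellGeometry:
    """Geometry of synthetic reporter cells (all circles, one image).

    The reference channel labels each whole cell uniformly with a brighter
    nucleus, enabling ROI segmentation; the reporter channel carries
    ``total_signal`` per cell split between nucleus and cytoplasm.
    """

    image_size: tuple[int, int] = (64, 64)
    centers: list[tuple[float, float]] = field(default_factory=lambda: [(32.0, 32.0)])
    cell_radius: float = 20.0
    nucleus_radius: float = 8.0
    total_signal: float = 50_000.0
    reference_background: float = 10.0
    reference_cell: float = 100.0
    reference_nucleus: float = 200.0

    def _disk(self, center: tuple[float, float], radius: float) -> np.ndarray:
        yy, xx = np.mgrid[0:self.image_size[0], 0:self.image_size[1]]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2

    def cell_mask(self, i: int = 0) -> np.ndarray:
        return self._disk(self.centers[i], self.cell_radius)

    def nuclear_mask(self, i: int = 0) -> np.ndarray:
        return self._disk(self.centers[i], self.nucleus_radius)


def render_translocation_image(nuclear_fraction: float,
                               cell_geometry: CellGeometry | None = None,
                               noise_sd: float = 2.0, seed: int = 0
                               ) -> tuple[np.ndarray, GroundTruth]:
    """Render a two-channel reporter/reference cell image.

    The requested ``nuclear_fraction`` f is defined on region-mean
    intensities as F_nuc / (F_nuc + F_cyto); each cell's reporter signal
    sums to ``total_signal`` (exactly, with noise off) while the nuclear and
    cytoplasmic mean intensities sit in the ratio f : (1 - f).

    Returns a float32 array of shape (2, H, W) — channel 0 the reporter,
    channel 1 the segmentation reference — and the ground truth.
    """
    f = nuclear_fraction
    if not 0.0 <= f <= 1.0:
        raise InvalidParameterError("nuclear_fraction must be in [0, 1]")
    geom = cell_geometry if cell_geometry is not None else CellGeometry()
    if geom.nucleus_radius >= geom.cell_radius:
        raise InvalidParameterError("nucleus must be strictly inside the cell")
    H, W = geom.image_size
    reporter = np.zeros((H, W), dtype=np.float64)
    reference = np.full((H, W), geom.reference_background, dtype=np.float64)
    for i in range(len(geom.centers)):
        cell = geom.cell_mask(i)
        nuc = geom.nuclear_mask(i)
        cyto = cell & ~nuc
        n_nuc, n_cyto = int(nuc.sum()), int(cyto.sum())
        # means m_n : m_c = f : (1 - f), with m_n*|N| + m_c*|C| = total_signal
        k = geom.total_signal / (f * n_nuc + (1.0 - f) * n_cyto)
        reporter[nuc] = f * k
        reporter[cyto] = (1.0 - f) * k
        reference[cell] = geom.reference_cell
        reference[nuc] = geom.reference_nucleus
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        reporter = reporter + rng.normal(0.0, noise_sd, size=(H, W))
        reference = reference + rng.normal(0.0, noise_sd, size=(H, W))
    image = np.stack([reporter, reference]).astype(np.float32)
    truth = GroundTruth(state_sequence=np.zeros(0, dtype=bool), true_bouts=[],
                        true_nuclear_fraction=f, seed=seed)
    return image, truth


# ---------------------------------------------------------------------------
# Dye-fed larva images
# ---------------------------------------------------------------------------


@dataclass
class BodyGeometry:
    """Geometry and palette of a synthetic dye-fed larva photograph."""

    image_size: tuple[int, int] = (120, 160)
    center: tuple[float, float] = (60.0, 80.0)
    semi_major: float = 50.0
    semi_minor: float = 16.0
    angle: float = 0.0
    body_color: tuple[int, int, int] = (120, 120, 70)
    stain_color: tuple[int, int, int] = (190, 40, 40)
    background_color: tuple[int, int, int] = (235, 235, 235)
    noise_sd: float = 3.0

    def body_mask(self) -> np.ndarray:
        yy, xx = np.mgrid[0:self.image_size[0], 0:self.image_size[1]].astype(float)
        dy, dx = yy - self.center[0], xx - self.center[1]
        u = dx * np.cos(self.angle) + dy * np.sin(self.angle)
        v = -dx * np.sin(self.angle) + dy * np.cos(self.angle)
        return (u / self.semi_major) ** 2 + (v / self.semi_minor) ** 2 <= 1.0


def render_dyed_larva(stain_fraction: float,
                      body_geometry: BodyGeometry | None = None,
                      seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Render a color image of a dye-fed larva on a light background.

    A contiguous anterior sub-region of the body, of area fraction
    ``stain_fraction``, is rendered in the stain color class (the dyed gut).
    Returns an (H, W, 3) uint8 image and the ground truth with the realised
    stained-area fraction.
    """
    s = stain_fraction
    if not 0.0 <= s <= 1.0:
        raise InvalidParameterError("stain_fraction must be in [0, 1]")
    geom = body_geometry if body_geometry is not None else BodyGeometry()
    H, W = geom.image_size
    body = geom.body_mask()
    n_body = int(body.sum())
    if n_body == 0:
        raise InvalidParameterError("body geometry renders no pixels")
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    axis_coord = ((xx - geom.center[1]) * np.cos(geom.angle)
                  + (yy - geom.center[0]) * np.sin(geom.angle))
    n_stain = int(round(s * n_body))
    stain = np.zeros((H, W), dtype=bool)
    if n_stain > 0:
        coords = axis_coord[body]
        order = np.argsort(coords, kind="stable")
        rr, cc = np.nonzero(body)
        sel = order[:n_stain]  # anterior-most pixels form a contiguous region
        stain[rr[sel], cc[sel]] = True
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = geom.background_color
    img[body] = geom.body_color
    img[stain] = geom.stain_color
    if geom.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, geom.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(state_sequence=np.zeros(0, dtype=bool), true_bouts=[],
                        true_stain_fraction=n_stain / n_body, seed=seed)
    return img, truth


# ---------------------------------------------------------------------------
# Sidecar output
# ---------------------------------------------------------------------------


def write_truth_sidecar(truth: GroundTruth, params: dict, csv_path: Path,
                        json_path: Path | None = None) -> None:
    """Write a truth CSV (frame_index, state, x_mm, y_mm) and a JSON sidecar
    with the generator parameters and seed."""
    df = trace_frame_table(truth.state_sequence, positions=truth.true_centroids)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {"seed": truth.seed, **params}
        json_path.write_text(json.dumps(payload, indent=2, default=str))


def motion_params_dict(motion: MotionParams) -> dict:
    return asdict(motion)
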