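"""Readers/writers and core containers for the formats the pipeline touches.

Covers frame stacks (multi-page TIFF or lexically ordered PNG/TIFF
directories), multi-well arena layouts, TriKinetics DAM2 monitor text files,
per-frame trace CSVs and per-animal metric CSVs.

Coordinate conventions used throughout the package: 0-based indices,
half-open intervals, pixel order (row, col) with the origin at the top-left.
Physical positions are reported as (x_mm, y_mm) where x runs along columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InvalidParameterError, OrderingError, ParseError

#: Rec. 601 luminance weights used for every RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: DAM2 status code marking a valid reading.
DAM2_VALID_STATUS = 1

#: Total number of tab-separated columns in a DAM2 record
#: (index, date, time, status, 6 metadata fields, 32 channel counts).
DAM2_N_COLUMNS = 42


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class FrameStack:
    """A time-lapse grayscale recording of one arena or one well.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W), uint8
        Pixel intensities in acquisition order.
    fps : float
        Frame rate in frames per second (0.87 for the larval rig).
    pixel_size_mm : float or None
        Optical calibration. When absent, distances degrade to pixel units
        and downstream outputs carry a ``px`` unit flag.
    """

    frames: np.ndarray
    fps: float
    pixel_size_mm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (T, H, W) array")
        if self.fps <= 0:
            raise InvalidParameterError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class WellBox:
    """Half-open bounding box ``[top, bottom) x [left, right)`` of one well."""

    row: int
    col: int
    top: int
    left: int
    bottom: int
    right: int

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclass
class WellGrid:
    """Rows x cols partition of an arena frame into well bounding boxes."""

    wells: list[WellBox]
    rows: int
    cols: int

    def __getitem__(self, rc: tuple[int, int]) -> WellBox:
        r, c = rc
        return self.wells[r * self.cols + c]

    def __iter__(self):
        return iter(self.wells)

    def __len__(self) -> int:
        return len(self.wells)


@dataclass
class DAMSeries:
    """Per-minute beam-crossing counts from a DAM monitor.

    ``counts`` is (n_minutes, n_channels); ``excluded`` flags minutes whose
    status code was not the valid reading code (those bins are ignored by the
    sleep scorer and break immobility runs rather than counting as zero).
    Clock positions are carried as minute-of-day integers so that bouts can
    be apportioned to the light and dark phase.
    """

    counts: np.ndarray
    channel_ids: list[int] = field(default_factory=lambda: [1])
    start: datetime | None = None
    start_minute_of_day: int = 9 * 60
    lights_on_min: int = 9 * 60
    lights_off_min: int = 21 * 60
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=np.int64))
        if self.counts.ndim == 2 and self.counts.shape[0] == 1 and len(self.channel_ids) == 1:
            # accept a 1-D series passed as a row vector
            self.counts = self.counts.reshape(-1, 1)
        if np.any(self.counts < 0):
            raise InvalidParameterError("beam-crossing counts must be non-negative")
        if self.excluded is None:
            self.excluded = np.zeros(self.counts.shape[0], dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape[0] != self.counts.shape[0]:
                raise InvalidParameterError("excluded mask length must match counts")

    @property
    def n_minutes(self) -> int:
        return self.counts.shape[0]

    def channel(self, channel_id: int) -> np.ndarray:
        return self.counts[:, self.channel_ids.index(channel_id)]


def parse_clock(text: str) -> int:
    """Parse an ``HH:MM`` clock string to a minute-of-day integer."""
    h, m = text.split(":")
    minute = int(h) * 60 + int(m)
    if not 0 <= minute < 24 * 60:
        raise InvalidParameterError(f"clock time out of range: {text!r}")
    return minute


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) image to 8-bit luminance (Rec. 601 weights)."""
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    rgb = image[..., :3].astype(np.float64)
    lum = rgb @ np.array(LUMA_WEIGHTS)
    return np.clip(np.round(lum), 0, 255).astype(np.uint8)


_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


def read_frame_stack(path: str | os.PathLike, fps: float,
                     pixel_size_mm: float | None = None) -> FrameStack:
    """Load a frame stack from a multi-page TIFF or a directory of frames.

    Directory frames are taken in lexical filename order (the acquisition
    software writes zero-padded frame numbers). RGB input is converted to
    luminance.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no frame files found in {p}")
        frames = []
        shape: tuple[int, int] | None = None
        for f in files:
            img = to_grayscale(np.asarray(iio.imread(f)))
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(
                    f"mixed frame dimensions: {f.name} is {img.shape}, expected {shape}")
            frames.append(img)
        stack = np.stack(frames)
    elif p.exists():
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4:  # (T, H, W, C) RGB pages
            arr = np.stack([to_grayscale(fr) for fr in arr])
        if arr.ndim != 3:
            raise FormatError(f"unsupported TIFF layout with shape {arr.shape}")
        stack = arr.astype(np.uint8, copy=False)
    else:
        raise FileNotFoundError(str(p))
    return FrameStack(stack, fps=fps, pixel_size_mm=pixel_size_mm)


def write_frame_stack(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a frame stack as a multi-page 8-bit grayscale TIFF."""
    tifffile.imwrite(Path(path), stack.frames.astype(np.uint8, copy=False))


# ---------------------------------------------------------------------------
# Well grids
# ---------------------------------------------------------------------------


def _equal_edges(n_pixels: int, n_cells: int) -> np.ndarray:
    return np.round(np.linspace(0, n_pixels, n_cells + 1)).astype(int)


def _refine_edges(profile: np.ndarray, edges: np.ndarray, search_px: int) -> np.ndarray:
    """Snap interior partition edges to nearby dark rim lines, if present.

    For each interior edge, the darkest position of the 1-D intensity
    profile within ``+-search_px`` is taken when it is clearly darker than
    the bulk of the profile (well rims image as dark lines); otherwise the
    equal-partition edge is kept.
    """
    refined = edges.copy()
    bulk = np.median(profile)
    for i in range(1, len(edges) - 1):
        lo = max(0, edges[i] - search_px)
        hi = min(len(profile), edges[i] + search_px + 1)
        window = profile[lo:hi]
        j = int(np.argmin(window))
        if window[j] < 0.8 * bulk:
            refined[i] = lo + j
    return refined


def detect_wells(frame: np.ndarray, rows: int = 4, cols: int = 6,
                 refine: bool = True, search_px: int = 8) -> WellGrid:
    """Partition an arena frame into a rows x cols grid of well boxes.

    Returns an equal partition by default; when dark well rims are
    detectable in the row/column intensity profiles, interior boundaries
    are snapped to the rim lines (within ``search_px``).
    """
    if rows < 1 or cols < 1:
        raise InvalidParameterError("rows and cols must be >= 1")
    H, W = frame.shape[:2]
    if rows > H or cols > W:
        raise InvalidParameterError(f"{rows}x{cols} grid larger than {H}x{W} frame")
    row_edges = _equal_edges(H, rows)
    col_edges = _equal_edges(W, cols)
    if refine and (rows > 1 or cols > 1):
        gray = to_grayscale(frame).astype(np.float64)
        row_edges = _refine_edges(gray.mean(axis=1), row_edges, search_px)
        col_edges = _refine_edges(gray.mean(axis=0), col_edges, search_px)
    wells = [
        WellBox(r, c, int(row_edges[r]), int(col_edges[c]),
                int(row_edges[r + 1]), int(col_edges[c + 1]))
        for r in range(rows) for c in range(cols)
    ]
    return WellGrid(wells, rows, cols)


# ---------------------------------------------------------------------------
# DAM2 monitor files
# ---------------------------------------------------------------------------

_DAM2_DATE_FMT = "%d %b %y"


def parse_dam2(text_lines: Iterable[str]) -> DAMSeries:
    """Parse DAM2 monitor text lines into a 32-channel count series.

    The dialect is the vendor's fixed 42-column tab-separated export:
    reading index, date, time, status, six metadata fields, then counts for
    channels 1-32. Rows whose status differs from the valid code are kept in
    the series but flagged excluded (they break immobility runs downstream).
    """
    rows: list[np.ndarray] = []
    excluded: list[bool] = []
    times: list[datetime] = []
    for lineno, raw in enumerate(text_lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != DAM2_N_COLUMNS:
            raise ParseError(
                f"expected {DAM2_N_COLUMNS} tab-separated fields, got {len(fields)}", lineno)
        try:
            stamp = datetime.strptime(f"{fields[1]} {fields[2]}", _DAM2_DATE_FMT + " %H:%M:%S")
        except ValueError as exc:
            raise ParseError(f"bad timestamp: {exc}", lineno) from None
        try:
            status = int(fields[3])
            counts = np.array([int(v) for v in fields[10:42]], dtype=np.int64)
        except ValueError:
            raise ParseError("non-integer count or status field", lineno) from None
        if times:
            if stamp <= times[-1]:
                raise OrderingError(
                    f"line {lineno}: timestamp {stamp} not after previous {times[-1]}")
            if stamp - times[-1] != timedelta(minutes=1):
                raise OrderingError(
                    f"line {lineno}: gap in timestamps ({times[-1]} -> {stamp}); "
                    "bins must be uniform 1-min")
        times.append(stamp)
        rows.append(counts)
        excluded.append(status != DAM2_VALID_STATUS)
    if not rows:
        raise FormatError("no DAM2 records found")
    start = times[0]
    return DAMSeries(
        counts=np.vstack(rows),
        channel_ids=list(range(1, 33)),
        start=start,
        start_minute_of_day=start.hour * 60 + start.minute,
        excluded=np.array(excluded),
    )


def read_dam2(path: str | os.PathLike) -> DAMSeries:
    with open(path, "r", encoding="ascii") as fh:
        return parse_dam2(fh)


def format_dam2(series: DAMSeries, start: datetime | None = None) -> list[str]:
    """Render a DAMSeries back into 42-column DAM2 text lines.

    Channels beyond those present in the series are written as zero counts
    so that the output is always a complete 32-channel record.
    """
    if start is None:
        start = series.start
    if start is None:
        day0 = datetime(2024, 1, 1)
        start = day0 + timedelta(minutes=series.start_minute_of_day)
    counts32 = np.zeros((series.n_minutes, 32), dtype=np.int64)
    for j, ch in enumerate(series.channel_ids):
        counts32[:, ch - 1] = series.counts[:, j]
    lines = []
    for i in range(series.n_minutes):
        stamp = start + timedelta(minutes=i)
        status = 51 if series.excluded is not None and series.excluded[i] else DAM2_VALID_STATUS
        meta = ["1", "0", "0", "0", "0", "0"]
        fields = [str(i + 1), stamp.strftime(_DAM2_DATE_FMT), stamp.strftime("%H:%M:%S"),
                  str(status), *meta, *[str(v) for v in counts32[i]]]
        lines.append("\t".join(fields))
    return lines


def write_dam2(series: DAMSeries, path: str | os.PathLike,
               start: datetime | None = None) -> None:
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(format_dam2(series, start)) + "\n")


# ---------------------------------------------------------------------------
# Trace / metrics CSVs
# ---------------------------------------------------------------------------

STATE_ACTIVE = "active"
STATE_INACTIVE = "inactive"


def trace_frame_table(states: Sequence[bool] | np.ndarray,
                      scores: np.ndarray | None = None,
                      positions: np.ndarray | None = None,
                      valid: np.ndarray | None = None) -> pd.DataFrame:
    """Build the per-frame trace table (frame_index, state[, score, x, y, valid])."""
    states = np.asarray(states, dtype=bool)
    data: dict[str, object] = {
        "frame_index": np.arange(len(states)),
        "state": np.where(states, STATE_ACTIVE, STATE_INACTIVE),
    }
    if scores is not None:
        data["score"] = np.asarray(scores)
    if positions is not None:
        pos = np.asarray(positions, dtype=float)
        data["x_mm"] = pos[:, 0]
        data["y_mm"] = pos[:, 1]
    if valid is not None:
        data["valid"] = np.asarray(valid, dtype=bool)
    return pd.DataFrame(data)


def write_trace_csv(obj, path: str | os.PathLike) -> None:
    """Write a trace or metrics object as CSV.

    Accepts a prepared DataFrame, a per-frame boolean state sequence, or a
    list of per-animal metric records (dicts). Round trips are lossless for
    integer and state fields and better than 1e-9 for floats.
    """
    if isinstance(obj, pd.DataFrame):
        df = obj
    elif isinstance(obj, (list, tuple)) and (not obj or isinstance(obj[0], dict)):
        df = pd.DataFrame(list(obj))
    else:
        df = trace_frame_table(np.asarray(obj, dtype=bool))
    df.to_csv(path, index=False)


def read_trace_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def states_from_table(df: pd.DataFrame) -> np.ndarray:
    """Recover the boolean active/inactive sequence from a trace table."""
    return (df["state"].to_numpy() == STATE_ACTIVE)
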