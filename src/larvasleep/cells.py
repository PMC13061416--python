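"""Quantification of reporter translocation, cytosolic marker intensity,
and the dye-based food-intake ratio.

The nuclear localization index (NLI) of a translocation-based calcium
reporter is computed per cell ROI as

    NLI = (F_nuc - F_cyto) / (F_nuc + F_cyto)

where F_nuc and F_cyto are background-subtracted mean reporter intensities
over the nuclear mask and the cytoplasmic mask (cell minus nucleus). Higher
values indicate more nuclear reporter, reflecting sustained Ca2+ activity.
ROIs come from an activity-insensitive reference channel that labels whole
cells with a brighter nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .errors import BodyNotFoundError, InvalidParameterError, InvalidROIError
from .io import LUMA_WEIGHTS

DEFAULT_MIN_CELL_AREA_PX = 30


@dataclass
class CellROI:
    """Nuclear and whole-cell pixel masks for one cell.

    The cytoplasm mask is the set difference cell \\ nucleus; it must be
    non-empty for NLI computation, otherwise the ROI is flagged invalid.
    """

    nuclear_mask: np.ndarray
    cell_mask: np.ndarray
    label: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        self.nuclear_mask = np.asarray(self.nuclear_mask, dtype=bool)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if (self.nuclear_mask & ~self.cell_mask).any():
            raise InvalidParameterError("nuclear mask must lie inside the cell mask")
        if not self.cytoplasm_mask.any():
            self.valid = False

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.nuclear_mask


@dataclass
class CellQuantResult:
    """Per-cell reporter quantification.

    NLI is NaN (undefined) when both region means are zero after background
    subtraction.
    """

    F_nuc: float
    F_cyto: float
    nli: float
    cytosolic_marker_intensity: float | None = None
    cell_id: int | None = None
    brain_id: str | None = None


def segment_cell_rois(reference_channel: np.ndarray,
                      min_cell_area_px: int = DEFAULT_MIN_CELL_AREA_PX
                      ) -> list[CellROI]:
    """Segment cell and nuclear ROIs from the reference channel.

    A two-level Otsu split of the intensity histogram separates background
    from cell and cell from (brighter) nucleus; connected components of the
    cell mask below ``min_cell_area_px`` are discarded. A blank image yields
    an empty list; a cell whose nucleus fills it entirely is flagged
    invalid.
    """
    img = np.asarray(reference_channel, dtype=np.float64)
    if np.ptp(img) == 0 or np.unique(img).size < 3:
        return []
    try:
        t_low, t_high = threshold_multiotsu(img, classes=3)
    except ValueError:
        return []
    cell_all = ndimage.binary_fill_holes(img > t_low)
    nuc_all = img > t_high
    labels, n = ndimage.label(cell_all)
    rois = []
    for i in range(1, n + 1):
        cell = labels == i
        if int(cell.sum()) < min_cell_area_px:
            continue
        rois.append(CellROI(nuclear_mask=nuc_all & cell, cell_mask=cell, label=i))
    return rois


def estimate_background(image: np.ndarray, rois: list[CellROI]) -> float:
    """Median intensity of pixels outside every cell mask."""
    img = np.asarray(image, dtype=np.float64)
    outside = np.ones(img.shape, dtype=bool)
    for roi in rois:
        outside &= ~roi.cell_mask
    if not outside.any():
        return 0.0
    return max(0.0, float(np.median(img[outside])))


def _region_mean(image: np.ndarray, mask: np.ndarray, background: float,
                 integrated: bool) -> float:
    vals = np.asarray(image, dtype=np.float64)[mask] - background
    stat = vals.sum() if integrated else vals.mean()
    return max(0.0, float(stat))


def compute_nli(reporter_channel: np.ndarray, roi: CellROI,
                background: float = 0.0, mode: str = "mean",
                cell_id: int | None = None,
                brain_id: str | None = None) -> CellQuantResult:
    """Compute F_nuc, F_cyto and the nuclear localization index for one ROI.

    ``mode='mean'`` (default) uses region-mean intensities, which keeps NLI
    in [-1, 1]; ``mode='integrated'`` sums intensities instead, provided
    for comparison.
    """
    if background < 0:
        raise InvalidParameterError("background must be >= 0")
    if mode not in ("mean", "integrated"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if not roi.cytoplasm_mask.any():
        raise InvalidROIError("cytoplasm mask is empty; cannot compute NLI")
    integrated = mode == "integrated"
    f_nuc = _region_mean(reporter_channel, roi.nuclear_mask, background, integrated)
    f_cyto = _region_mean(reporter_channel, roi.cytoplasm_mask, background, integrated)
    denom = f_nuc + f_cyto
    if denom == 0:
        warnings.warn("zero reporter signal in both regions; NLI undefined",
                      RuntimeWarning, stacklevel=2)
        nli = float("nan")
    else:
        nli = (f_nuc - f_cyto) / denom
    return CellQuantResult(F_nuc=f_nuc, F_cyto=f_cyto, nli=nli,
                           cell_id=cell_id, brain_id=brain_id)


def cytosolic_intensity(marker_channel: np.ndarray, roi: CellROI,
                        background: float = 0.0) -> float:
    """Background-subtracted mean marker intensity over the cytoplasm
    (nucleus excluded), as used for per-cell peptide accumulation."""
    if not roi.cytoplasm_mask.any():
        raise InvalidROIError("cytoplasm mask is empty")
    return _region_mean(marker_channel, roi.cytoplasm_mask, background,
                        integrated=False)


# ---------------------------------------------------------------------------
# Dye-based food intake
# ---------------------------------------------------------------------------


@dataclass
class StainColorModel:
    """Stain pixel rule: red channel exceeds both others by ``red_excess_min``."""

    red_excess_min: float = 40.0

    def mask(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        return img[..., 0] - np.maximum(img[..., 1], img[..., 2]) > self.red_excess_min


@dataclass
class BodyIntensityModel:
    """Body pixel rule: luminance below ``max_luminance`` (dark animal on a
    light background)."""

    max_luminance: float = 180.0

    def mask(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        lum = img[..., :3] @ np.array(LUMA_WEIGHTS)
        return lum < self.max_luminance


def dye_intake_ratio(image: np.ndarray,
                     stain_color_model: StainColorModel | None = None,
                     body_intensity_model: BodyIntensityModel | None = None,
                     min_body_area_px: int = 50) -> float:
    """Dye-stained area over total body area for one larva image.

    When several body-sized components are present, the largest is used and
    a warning is emitted (the assay photographs one larva per image).
    """
    stain_model = stain_color_model or StainColorModel()
    body_model = body_intensity_model or BodyIntensityModel()
    body_all = ndimage.binary_fill_holes(body_model.mask(image))
    labels, n = ndimage.label(body_all)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1)) if n else np.array([])
    big = np.flatnonzero(sizes >= min_body_area_px)
    if big.size == 0:
        raise BodyNotFoundError("no larval body detected")
    if big.size > 1:
        warnings.warn(f"{big.size} body-sized components; using the largest",
                      RuntimeWarning, stacklevel=2)
    body = labels == (1 + int(big[np.argmax(sizes[big])]))
    stain = stain_model.mask(image) & body
    return float(stain.sum()) / float(body.sum())


def pool_cells(results: list[CellQuantResult],
               brain_ids: list[str] | None = None) -> pd.DataFrame:
    """Pool per-cell results across brains into one flat table.

    Cells are the statistical unit: pooling concatenates rows and retains
    the brain id; no per-brain averaging is performed.
    """
    if brain_ids is not None:
        if len(brain_ids) != len(results):
            raise InvalidParameterError("brain_ids must align with results")
        for r, b in zip(results, brain_ids):
            r.brain_id = b
    rows = [{
        "brain_id": r.brain_id,
        "cell_id": r.cell_id,
        "F_nuc": r.F_nuc,
        "F_cyto": r.F_cyto,
        "NLI": r.nli,
        "cytosolic_intensity": r.cytosolic_marker_intensity,
    } for r in results]
    return pd.DataFrame(rows, columns=["brain_id", "cell_id", "F_nuc",
                                       "F_cyto", "NLI", "cytosolic_intensity"])
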