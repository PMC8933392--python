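"""Percent-positive scoring of H-DAB immunohistochemistry images.

The scorer converts a brightfield RGB field of view to optical density,
unmixes hematoxylin and DAB, detects nuclei as connected components above a
uniform hematoxylin OD threshold (default 0.3), measures mean DAB OD in each
nucleus and in a cytoplasmic annulus around it, and calls a cell DAB-positive
when either compartment exceeds the DAB threshold. The section score is

    percent positive = 100 * (DAB-positive cells) / (hematoxylin cells)

per region of interest (ROI), aggregated as mean +/- sample SD over the
(typically three) ROIs of a section.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

from .errors import UndefinedScoreError, ValidationError
from .stains import StainVectorSet, deconvolve_stains, rgb_to_od


@dataclass
class StainedImage:
    """One brightfield RGB field of view (H x W x 3, 8-bit)."""

    pixels: np.ndarray
    microns_per_pixel: float | None = None
    roi_id: str = ""
    section_id: str = ""
    sample_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("pixels must be an HxWx3 array with H, W >= 1")
        self.pixels = px


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and geometry for the IHC scorer.

    Thresholds are in optical-density units: ``hema_threshold`` calls
    hematoxylin (nucleus) positivity per pixel, ``dab_threshold`` calls DAB
    positivity on compartment mean OD. Both default to the uniform 0.3 used
    across samples. All threshold comparisons are strict (>): ties fall
    negative.
    """

    hema_threshold: float = 0.3
    dab_threshold: float = 0.3
    min_nucleus_area_px: int = 20
    annulus_width_px: int = 3
    background_rgb: tuple = (255.0, 255.0, 255.0)
    stain_vectors: StainVectorSet = field(default_factory=StainVectorSet)
    watershed_split: bool = True
    watershed_min_distance: int = 5

    def __post_init__(self):
        if self.hema_threshold <= 0 or self.dab_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.min_nucleus_area_px < 1 or self.annulus_width_px < 1:
            raise ValidationError("area and annulus width must be >= 1")


@dataclass(frozen=True)
class CellDetection:
    """One detected nucleus with compartment OD summaries and the DAB call."""

    cell_id: int
    centroid: tuple
    nucleus_area_px: int
    nucleus_mean_hema_od: float
    nucleus_mean_dab_od: float
    cytoplasm_mean_dab_od: float
    dab_positive: bool


@dataclass(frozen=True)
class RoiScore:
    roi_id: str
    n_hema_cells: int
    n_dab_cells: int
    percent_positive: float | None


@dataclass(frozen=True)
class SectionScore:
    """Per-ROI counts plus the three-ROI mean +/- sample SD of the section."""

    section_id: str
    roi_scores: tuple
    mean_percent_positive: float
    sd_percent_positive: float
    n_rois_used: int
    flags: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "roi_id": r.roi_id,
                "n_hema": r.n_hema_cells,
                "n_dab": r.n_dab_cells,
                "percent_positive": r.percent_positive,
            }
            for r in self.roi_scores
        ]
        return pd.DataFrame(rows)


def _label_nuclei(hema_map: np.ndarray, config: ScoringConfig) -> np.ndarray:
    mask = hema_map > config.hema_threshold
    mask = opening(mask, footprint=np.ones((3, 3), bool))
    if not mask.any():
        return np.zeros_like(mask, dtype=np.int32)
    if config.watershed_split:
        distance = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            distance, min_distance=config.watershed_min_distance, labels=mask
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if markers.max() == 0:
            labels, _ = ndi.label(mask)
        else:
            labels = watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndi.label(mask)
    return labels


def nucleus_label_mask(image: StainedImage, config: ScoringConfig | None = None) -> np.ndarray:
    """Labeled nucleus mask (int32, 0 = background) for QC overlays."""
    config = config or ScoringConfig()
    od = rgb_to_od(image.pixels, config.background_rgb)
    hema, _, _ = deconvolve_stains(od, config.stain_vectors)
    return _label_nuclei(np.asarray(hema, dtype=float), config)


def detect_cells(hema_map, dab_map, config: ScoringConfig | None = None) -> list[CellDetection]:
    """Detect nuclei on the hematoxylin map and call DAB positivity per cell.

    A cell is DAB positive if mean DAB OD exceeds ``dab_threshold`` in either
    the nucleus or a cytoplasmic annulus of ``annulus_width_px`` around it
    (pixels belonging to any nucleus are excluded from the annulus).
    """
    config = config or ScoringConfig()
    hema_map = np.asarray(hema_map, dtype=float)
    dab_map = np.asarray(dab_map, dtype=float)
    if hema_map.shape != dab_map.shape:
        raise ValidationError("hematoxylin and DAB maps must have the same shape")
    labels = _label_nuclei(hema_map, config)
    if labels.max() == 0:
        return []
    any_nucleus = labels > 0
    footprint = disk(config.annulus_width_px)
    detections: list[CellDetection] = []
    objects = ndi.find_objects(labels)
    cell_id = 0
    w = config.annulus_width_px
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = labels[sl] == lab
        area = int(region.sum())
        if area < config.min_nucleus_area_px:
            continue
        rows, cols = np.nonzero(region)
        centroid = (float(rows.mean() + sl[0].start), float(cols.mean() + sl[1].start))
        nuc_hema = float(hema_map[sl][region].mean())
        nuc_dab = float(dab_map[sl][region].mean())
        # annulus computed in a padded bounding box so dilation is not cropped
        psl = (
            slice(max(sl[0].start - w, 0), min(sl[0].stop + w, labels.shape[0])),
            slice(max(sl[1].start - w, 0), min(sl[1].stop + w, labels.shape[1])),
        )
        pregion = labels[psl] == lab
        ring = ndi.binary_dilation(pregion, structure=footprint) & ~any_nucleus[psl]
        cyto_dab = float(dab_map[psl][ring].mean()) if ring.any() else 0.0
        cell_id += 1
        positive = (nuc_dab > config.dab_threshold) or (cyto_dab > config.dab_threshold)
        detections.append(
            CellDetection(
                cell_id=cell_id,
                centroid=centroid,
                nucleus_area_px=area,
                nucleus_mean_hema_od=nuc_hema,
                nucleus_mean_dab_od=nuc_dab,
                cytoplasm_mean_dab_od=cyto_dab,
                dab_positive=positive,
            )
        )
    return detections


def apply_dab_threshold(detections: Sequence[CellDetection], dab_threshold: float) -> list[CellDetection]:
    """Re-call DAB positivity on existing detections at a different threshold.

    Detection geometry depends only on the hematoxylin threshold, so sweeping
    DAB candidates only requires re-thresholding the stored compartment means.
    """
    if dab_threshold <= 0:
        raise ValidationError("dab_threshold must be positive")
    return [
        replace(
            d,
            dab_positive=(d.nucleus_mean_dab_od > dab_threshold)
            or (d.cytoplasm_mean_dab_od > dab_threshold),
        )
        for d in detections
    ]


def percent_positive(n_dab: int, n_hema: int) -> float:
    """Percent positive = 100 * DAB-positive cells / hematoxylin cells."""
    if n_hema == 0:
        raise UndefinedScoreError("percent positive undefined: no hematoxylin-positive cells")
    if n_dab < 0 or n_hema < 0:
        raise ValidationError("counts must be nonnegative")
    if n_dab > n_hema:
        raise ValidationError("DAB-positive count cannot exceed hematoxylin count")
    return 100.0 * n_dab / n_hema


def measure_image(image: StainedImage, config: ScoringConfig | None = None) -> list[CellDetection]:
    """Full per-image pipeline: OD conversion, unmixing, cell detection."""
    config = config or ScoringConfig()
    od = rgb_to_od(image.pixels, config.background_rgb)
    hema, dab, _ = deconvolve_stains(od, config.stain_vectors)
    return detect_cells(hema, dab, config)


def score_roi(image: StainedImage, config: ScoringConfig | None = None) -> RoiScore:
    detections = measure_image(image, config)
    n_hema = len(detections)
    n_dab = sum(d.dab_positive for d in detections)
    pct = percent_positive(n_dab, n_hema) if n_hema > 0 else None
    return RoiScore(roi_id=image.roi_id, n_hema_cells=n_hema, n_dab_cells=n_dab, percent_positive=pct)


def score_section(rois: Sequence[StainedImage], config: ScoringConfig | None = None,
                  section_id: str = "") -> SectionScore:
    """Score each ROI and aggregate to the section mean +/- sample SD.

    ROIs with zero hematoxylin cells are flagged and excluded from the
    aggregate; a single usable ROI reports SD = 0 with a flag.
    """
    if len(rois) == 0:
        raise ValidationError("at least one ROI is required")
    flags = []
    if len(rois) != 3:
        warnings.warn(f"expected 3 ROIs per section, got {len(rois)}", stacklevel=2)
        flags.append(f"n_rois={len(rois)}")
    roi_scores = [score_roi(img, config) for img in rois]
    usable = [r for r in roi_scores if r.percent_positive is not None]
    for r in roi_scores:
        if r.percent_positive is None:
            warnings.warn(f"ROI {r.roi_id!r} had no hematoxylin cells; excluded", stacklevel=2)
            flags.append(f"roi_excluded:{r.roi_id}")
    if not usable:
        raise UndefinedScoreError("no ROI produced a defined percent positive")
    values = np.array([r.percent_positive for r in usable], dtype=float)
    if len(values) == 1:
        mean, sd = float(values[0]), 0.0
        flags.append("sd_undefined_single_roi")
    else:
        mean, sd = float(values.mean()), float(values.std(ddof=1))
    sid = section_id or (rois[0].section_id if rois[0].section_id else "")
    return SectionScore(
        section_id=sid,
        roi_scores=tuple(roi_scores),
        mean_percent_positive=mean,
        sd_percent_positive=sd,
        n_rois_used=len(usable),
        flags=tuple(flags),
    )


def detections_to_frame(detections: Sequence[CellDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": d.cell_id,
                "centroid_row": d.centroid[0],
                "centroid_col": d.centroid[1],
                "nucleus_area_px": d.nucleus_area_px,
                "nucleus_mean_hema_od": d.nucleus_mean_hema_od,
                "nucleus_mean_dab_od": d.nucleus_mean_dab_od,
                "cytoplasm_mean_dab_od": d.cytoplasm_mean_dab_od,
                "dab_positive": d.dab_positive,
            }
            for d in detections
        ]
    )
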