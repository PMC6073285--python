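"""Per-NMJ fluorescence accumulation analysis on 2D sections.

A neuromuscular junction is scored immunopositive for a marker when the
marker fluorescence accumulates at the junction above the surrounding
muscle-fiber level.  The procedure mirrors the classic ImageJ workflow:

1. median-filter the postsynapse (α-bungarotoxin, BGT) channel with a
   1-pixel-radius kernel;
2. threshold it at 30–255 grayscale and take 8-connected components as
   NMJ regions of interest (ROIs);
3. for each ROI, define a paired muscle-fiber reference region — here a
   dilation ring around the ROI, since the original free-hand fiber
   outline is not reproducible programmatically;
4. measure mean and SD of the *marker* channel in both regions and call
   the NMJ positive iff  mean_NMJ > mean_fiber + sd_fiber  (strict).

The call compares a region mean against a mean-plus-one-SD background
band, so it is invariant under any positive affine rescaling of the
marker channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, ValidationError
from .volumes import ResultsTable, VolumeImage


@dataclass
class AccumulationConfig:
    """Parameters of the accumulation analysis.

    ``median_kernel_radius`` of 1 means a 3×3 median (the ImageJ
    "radius 1" convention).  ``bgt_threshold`` bounds are inclusive.
    ``fiber_ring_radius_px`` sets the width of the square-dilation ring
    that stands in for the fiber reference region; ``min_roi_area_px``
    discards specks that no rater would outline as a junction.
    """

    median_kernel_radius: int = 1
    bgt_threshold: tuple[int, int] = (30, 255)
    min_roi_area_px: int = 20
    fiber_ring_radius_px: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.bgt_threshold
        if not (0 <= lo <= hi <= 255):
            raise ConfigurationError("bgt_threshold must satisfy 0<=lo<=hi<=255")
        if self.median_kernel_radius < 0:
            raise ConfigurationError("median_kernel_radius must be >= 0")
        if self.min_roi_area_px < 1 or self.fiber_ring_radius_px < 1:
            raise ConfigurationError("area and ring radius must be >= 1")


@dataclass(frozen=True)
class RegionStats:
    """First two moments of the intensities inside a region."""

    mean_grey: float
    sd_grey: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValidationError("region statistics need at least one pixel")
        if self.sd_grey < 0:
            raise ValidationError("sd_grey must be non-negative")


def region_stats(image: np.ndarray, mask: np.ndarray) -> RegionStats:
    """Mean/SD of image intensities under a boolean mask (population SD)."""
    values = np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)]
    if values.size == 0:
        raise ValidationError("empty region")
    return RegionStats(
        mean_grey=float(values.mean()),
        sd_grey=float(values.std(ddof=0)),
        n_pixels=int(values.size),
    )


def median_filter(image: np.ndarray, radius: int = 1) -> np.ndarray:
    """Median over the (2r+1)² neighborhood; borders replicate edges.

    Radius 0 is the identity.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    if radius == 0:
        return np.asarray(image).copy()
    return ndimage.median_filter(image, size=2 * radius + 1, mode="nearest")


def extract_nmj_rois(
    bgt_image: np.ndarray, cfg: AccumulationConfig | None = None
) -> list[np.ndarray]:
    """NMJ ROI masks from the median-filtered postsynapse channel.

    Pixels within the inclusive threshold band form a mask whose
    8-connected components of sufficient area become ROIs, returned in
    centroid order (y, then x) for determinism.  No ROI is not an
    error: the caller flags the section and moves on.
    """
    cfg = cfg or AccumulationConfig()
    img = np.asarray(bgt_image)
    if img.ndim != 2:
        raise ValidationError(f"expected a 2D section, got {img.ndim}D")
    lo, hi = cfg.bgt_threshold
    mask = (img >= lo) & (img <= hi)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    rois: list[tuple[tuple[float, float], np.ndarray]] = []
    for i in range(1, n + 1):
        roi = labels == i
        if roi.sum() < cfg.min_roi_area_px:
            continue
        ys, xs = np.nonzero(roi)
        rois.append(((float(ys.mean()), float(xs.mean())), roi))
    rois.sort(key=lambda item: item[0])
    return [roi for _, roi in rois]


def fiber_region_for(
    roi: np.ndarray,
    cfg: AccumulationConfig | None = None,
    all_rois: list[np.ndarray] | None = None,
) -> np.ndarray | None:
    """Muscle-fiber reference region paired with one NMJ ROI.

    The ROI is dilated by a square structuring element of radius
    ``fiber_ring_radius_px``; the ring (dilation minus the ROI itself,
    minus every pixel of any other ROI) is the fiber region.  Returns
    None when the ring is empty — the caller flags the NMJ as
    "undefined fiber region" and excludes it from denominators.
    """
    cfg = cfg or AccumulationConfig()
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValidationError("fiber_region_for requires a non-empty ROI")
    r = cfg.fiber_ring_radius_px
    struct = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    ring = ndimage.binary_dilation(roi, structure=struct) & ~roi
    if all_rois is not None:
        for other in all_rois:
            if other is roi or np.array_equal(other, roi):
                continue
            ring &= ~np.asarray(other, dtype=bool)
    if not ring.any():
        return None
    return ring


def classify_accumulation(nmj: RegionStats, fiber: RegionStats) -> bool:
    """Positive iff the NMJ mean strictly exceeds fiber mean + fiber SD."""
    return nmj.mean_grey > fiber.mean_grey + fiber.sd_grey


@dataclass
class AccumulationResult:
    """Per-NMJ calls plus the summary percentage for one section."""

    table: ResultsTable
    n_analyzed: int
    n_positive: int
    n_flagged: int

    @property
    def percent_positive(self) -> float:
        """Positives as percent of analyzed (unflagged) NMJs."""
        if self.n_analyzed == 0:
            return float("nan")
        return 100.0 * self.n_positive / self.n_analyzed


def accumulation_study(
    volume: VolumeImage,
    marker_channel: str,
    cfg: AccumulationConfig | None = None,
    postsynapse_channel: str = "BGT",
) -> AccumulationResult:
    """Run the full accumulation analysis on one 2D section.

    The postsynapse channel defines the ROIs; statistics and the
    positivity call are computed on the marker channel.  NMJs whose
    fiber ring is empty are flagged and excluded from the percentage
    denominator rather than silently dropped.
    """
    cfg = cfg or AccumulationConfig()
    if not volume.is_2d:
        raise ValidationError("accumulation analysis expects a single section")
    bgt = median_filter(volume.channel(postsynapse_channel)[0], cfg.median_kernel_radius)
    marker = volume.channel(marker_channel)[0]
    rois = extract_nmj_rois(bgt, cfg)

    rows = []
    n_pos = n_flag = 0
    for i, roi in enumerate(rois, start=1):
        ring = fiber_region_for(roi, cfg, all_rois=rois)
        nmj_stats = region_stats(marker, roi)
        if ring is None:
            n_flag += 1
            rows.append(
                {
                    "nmj_id": i,
                    "n_pixels": nmj_stats.n_pixels,
                    "mean_nmj": nmj_stats.mean_grey,
                    "sd_nmj": nmj_stats.sd_grey,
                    "flagged": True,
                    "positive": pd.NA,
                }
            )
            continue
        fiber_stats = region_stats(marker, ring)
        positive = classify_accumulation(nmj_stats, fiber_stats)
        n_pos += int(positive)
        rows.append(
            {
                "nmj_id": i,
                "n_pixels": nmj_stats.n_pixels,
                "mean_nmj": nmj_stats.mean_grey,
                "sd_nmj": nmj_stats.sd_grey,
                "mean_fiber": fiber_stats.mean_grey,
                "sd_fiber": fiber_stats.sd_grey,
                "positive": positive,
                "flagged": False,
            }
        )

    table = ResultsTable(
        records=pd.DataFrame(rows),
        metadata={
            "marker": marker_channel,
            "n_rois": len(rois),
            "n_flagged": n_flag,
            "no_rois": len(rois) == 0,
        },
    )
    return AccumulationResult(
        table=table,
        n_analyzed=len(rois) - n_flag,
        n_positive=n_pos,
        n_flagged=n_flag,
    )
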