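"""Semi-automated segmentation and morphometrics of fluorescent domains.

The workflow mirrors the interactive one used on real data: remove the
diffuse background with a large-radius morphological opening (the classic
rolling-ball background of interactive tools), enhance punctate contrast
with a large-radius unsharp mask, threshold the filtered image into a
mask, then measure each connected domain — area, mean intensity — on the
background-subtracted (not the contrast-enhanced) image.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from .config import SegmentationParams
from .types import Domain, Movie

log = logging.getLogger(__name__)

__all__ = [
    "subtract_background",
    "unsharp_mask",
    "make_mask",
    "measure_domains",
    "domains_per_cell",
    "segment_frame",
    "segment_movie",
    "domains_to_frame",
]

# disk footprints above this radius use skimage's sequence decomposition,
# an octagonal approximation that is orders of magnitude faster and
# deviates from the exact disk by <0.2% on unit-scale images
_DECOMPOSE_RADIUS = 12


def _disk_footprint(radius_px: int):
    if radius_px >= _DECOMPOSE_RADIUS:
        return morphology.disk(radius_px, decomposition="sequence")
    return morphology.disk(radius_px)


def subtract_background(frame: np.ndarray, radius_px: int) -> np.ndarray:
    """Remove the smooth background estimated by grey opening with a disk.

    The opening never exceeds the input, so the result is non-negative; a
    flat field maps to zero everywhere.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(frame.shape):
        raise ValueError("background radius must be smaller than the image")
    background = morphology.opening(frame, footprint=_disk_footprint(radius_px))
    return np.clip(frame - background, 0.0, None)


def unsharp_mask(frame: np.ndarray, radius_px: float, amount: float) -> np.ndarray:
    """Locally enhance contrast: ``out = in + amount·(in − G_radius(in))``."""
    frame = np.asarray(frame, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    blurred = ndimage.gaussian_filter(frame, sigma=radius_px, mode="reflect")
    return frame + amount * (frame - blurred)


def make_mask(filtered: np.ndarray, threshold: float | str) -> np.ndarray:
    """Binary mask ``filtered >= threshold``; ``"otsu"`` picks it automatically."""
    filtered = np.asarray(filtered, dtype=float)
    if not np.all(np.isfinite(filtered)):
        raise ValueError("filtered image must be finite")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError("threshold must be a number or 'otsu'")
        threshold = float(filters.threshold_otsu(filtered))
    mask = filtered >= threshold
    if mask.all() or not mask.any():
        warnings.warn("threshold outside image range: mask is empty or full")
    return mask


def measure_domains(
    mask: np.ndarray,
    bg_subtracted: np.ndarray,
    params: SegmentationParams,
    frame: int = 0,
    pixel_size_um: float | None = None,
) -> list[Domain]:
    """8-connected mask components of sufficient area, measured on the
    background-subtracted image.  Labels are assigned in raster order of
    each component's first (top-most, then left-most) pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    bg_subtracted = np.asarray(bg_subtracted, dtype=float)
    if mask.shape != bg_subtracted.shape:
        raise ValueError("mask and intensity image must share a shape")
    labelled = measure.label(mask, connectivity=2)
    domains: list[Domain] = []
    for region in measure.regionprops(labelled, intensity_image=bg_subtracted):
        if region.area < params.min_area_px:
            continue
        cr, cc = region.centroid
        domains.append(
            Domain(
                label=len(domains) + 1,
                frame=frame,
                area_px=int(region.area),
                area_um2=float(region.area) * (pixel_size_um**2 if pixel_size_um else np.nan),
                mean_intensity=float(region.intensity_mean),
                centroid_row_px=float(cr),
                centroid_col_px=float(cc),
            )
        )
    return domains


def domains_per_cell(domains: list[Domain], cell_mask: np.ndarray) -> dict[int, int]:
    """Count domains per cell by the cell label under each domain centroid.

    Centroids falling on label 0 (no cell) are dropped; the dropped count
    is logged.  Cells present in the mask but containing no domain are
    reported with count 0.
    """
    cell_mask = np.asarray(cell_mask)
    if cell_mask.ndim != 2:
        raise ValueError("cell_mask must be a 2-D label image")
    if (cell_mask < 0).any():
        raise ValueError("cell labels must be >= 0")
    counts = {int(lbl): 0 for lbl in np.unique(cell_mask) if lbl > 0}
    dropped = 0
    for d in domains:
        r = int(round(d.centroid_row_px))
        c = int(round(d.centroid_col_px))
        if not (0 <= r < cell_mask.shape[0] and 0 <= c < cell_mask.shape[1]):
            raise ValueError("domain centroid outside the cell mask")
        lbl = int(cell_mask[r, c])
        if lbl == 0:
            dropped += 1
        else:
            counts[lbl] = counts.get(lbl, 0) + 1
    if dropped:
        log.info("domains_per_cell: dropped %d domain(s) outside any cell", dropped)
    return counts


def segment_frame(
    frame: np.ndarray, params: SegmentationParams, frame_index: int = 0,
    pixel_size_um: float | None = None,
) -> tuple[list[Domain], np.ndarray, np.ndarray]:
    """Full single-frame segmentation; returns (domains, mask, bg_subtracted)."""
    params.validate()
    bg_sub = subtract_background(frame, params.background_radius_px)
    enhanced = unsharp_mask(bg_sub, params.unsharp_radius_px, params.unsharp_amount)
    mask = make_mask(enhanced, params.threshold)
    domains = measure_domains(
        mask, bg_sub, params, frame=frame_index, pixel_size_um=pixel_size_um
    )
    return domains, mask, bg_sub


def segment_movie(
    movie: Movie,
    params: SegmentationParams,
    frames: list[int] | None = None,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Segment selected frames of a movie into a tidy domain table."""
    if frames is None:
        frames = list(range(movie.n_frames))
    rows = []
    for t in frames:
        domains, _, _ = segment_frame(
            movie.data[t].astype(float), params, frame_index=t,
            pixel_size_um=movie.pixel_size_um,
        )
        if cell_mask is not None:
            assigned = []
            for d in domains:
                r = int(round(d.centroid_row_px))
                c = int(round(d.centroid_col_px))
                lbl = int(cell_mask[r, c])
                assigned.append(
                    Domain(d.label, d.frame, d.area_px, d.area_um2, d.mean_intensity,
                           d.centroid_row_px, d.centroid_col_px,
                           cell_id=lbl if lbl > 0 else None)
                )
            domains = assigned
        rows.extend(domains)
    return domains_to_frame(rows)


def domains_to_frame(domains: list[Domain]) -> pd.DataFrame:
    cols = ["frame", "label", "area_px", "area_um2", "mean_intensity",
            "centroid_row_px", "centroid_col_px", "cell_id"]
    return pd.DataFrame(
        [{c: getattr(d, c) for c in cols} for d in domains], columns=cols
    )
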