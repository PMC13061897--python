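"""Colony segmentation from plate images and pixel-to-mm conversion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu


@dataclass
class Contour:
    label: int
    area_px: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:  # RGB(A) -> luminance
        img = img[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    return img.astype(float)


def binarize(gray: np.ndarray, threshold: float | str = "otsu",
             foreground_bright: bool = True) -> np.ndarray:
    """Binarize with a fixed value, Otsu, or the median/max midpoint.

    ``'midmax'`` thresholds halfway between the image median and extremum;
    robust when foreground covers a tiny pixel fraction (where Otsu splits
    inside the background noise).
    """
    if isinstance(threshold, str):
        if np.ptp(gray) == 0:
            return np.zeros_like(gray, dtype=bool)
        if threshold == "otsu":
            thr = threshold_otsu(gray)
        elif threshold == "midmax":
            extremum = gray.max() if foreground_bright else gray.min()
            thr = (np.median(gray) + extremum) / 2.0
        else:
            raise ValueError("threshold must be a number, 'otsu' or 'midmax'")
    else:
        thr = float(threshold)
    return gray > thr if foreground_bright else gray < thr


def segment_colonies(
    image: np.ndarray,
    threshold: float | str = "otsu",
    min_area_px: float = 50.0,
    foreground_bright: bool = True,
    exclude_rim: bool = True,
    roi_split_x: float | None = None,
) -> list[Contour]:
    """Segment colonies: grayscale -> binarize -> connected components.

    Components (8-connectivity) smaller than ``min_area_px`` are dropped;
    the plate rim (a thin ring touching the largest extent) is removed when
    ``exclude_rim`` by discarding components whose bounding-box diagonal
    exceeds half the image diagonal with low fill ratio. ``roi_split_x``
    splits every component at a vertical line (the inter-inoculum midline)
    before labelling, to separate touching colonies. Returns contours
    sorted by area descending.
    """
    gray = to_grayscale(image)
    if gray.size == 0:
        return []
    mask = binarize(gray, threshold, foreground_bright)
    if roi_split_x is not None:
        x = int(round(roi_split_x))
        if 0 <= x < mask.shape[1]:
            mask = mask.copy()
            mask[:, x] = False
    labels = measure.label(mask, connectivity=2)
    out: list[Contour] = []
    img_diag = float(np.hypot(*gray.shape))
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        if exclude_rim:
            h = rp.bbox[2] - rp.bbox[0]
            w = rp.bbox[3] - rp.bbox[1]
            fill = rp.area / max(h * w, 1)
            if np.hypot(h, w) > 0.5 * img_diag and fill < 0.3:
                continue  # thin ring spanning the plate: the rim
        out.append(
            Contour(
                label=int(rp.label),
                area_px=float(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=tuple(int(v) for v in rp.bbox),
            )
        )
    out.sort(key=lambda c: -c.area_px)
    return out


def px_to_mm_factor(plate_diameter_px: float, plate_diameter_mm: float) -> float:
    """Linear conversion factor c (mm/px); areas convert with c**2."""
    if plate_diameter_px <= 0 or plate_diameter_mm <= 0:
        raise ValueError("plate diameters must be > 0")
    return plate_diameter_mm / plate_diameter_px


def area_mm2(area_px: float, c: float) -> float:
    return area_px * c * c


def estimate_plate_diameter_px(image: np.ndarray,
                               threshold: float | str = "midmax") -> float:
    """Estimate the rim diameter as the largest extent of foreground pixels.

    The rim encloses all colonies, so the bounding box of all thresholded
    pixels spans the rim; the diameter is the mean of its width and height.
    """
    gray = to_grayscale(image)
    mask = binarize(gray, threshold, foreground_bright=True)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("no foreground pixels; cannot locate the plate rim")
    return float(((ys.max() - ys.min() + 1) + (xs.max() - xs.min() + 1)) / 2.0)
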