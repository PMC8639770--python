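"""Classical focus segmentation and the MD / ED / WPD hand-crafted features.

The non-CNN branch of the focus classifier works on three numbers computed
from the segmented focus region of a Giemsa micrograph:

* **MD** — median grayscale value of the region (basophilic foci are dark,
  so transformed foci have low MD);
* **ED** — equivalent diameter, the diameter of the circle with the same
  area as the region, ``ED = sqrt(4*AREA/pi)``;
* **WPD** — weighted perimeter difference,
  ``(FRP - EFP) * (AREA - AREA_min) / (AREA_max - AREA_min)``,
  where FRP is the measured region perimeter, ``EFP = pi * ED`` the
  perimeter of the equal-area circle, and AREA_min/AREA_max are the extreme
  region areas observed in the training data.  WPD grows with border
  irregularity (invasiveness), up-weighted for large foci.

Segmentation: the image is converted to HSV; the saturation channel
(quantized to 256 bins) is thresholded by discriminant analysis (Otsu's
method); pixels above the threshold are foreground, and the largest
8-connected component is taken as the focus region — each micrograph is
centred on a single candidate focus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.measure import label as cc_label
from skimage.measure import perimeter as region_perimeter

from .synthgen import DatasetManifest, FocusImage, images_for

__all__ = [
    "SegmentedRegion",
    "FeatureVector",
    "FeatureScaler",
    "DegenerateImageError",
    "NoFocusRegionError",
    "otsu_threshold",
    "segment_focus",
    "compute_features",
    "fit_scaler",
    "extract_batch",
]


class DegenerateImageError(ValueError):
    """Single-valued histogram: no threshold separates two classes."""


class NoFocusRegionError(ValueError):
    """Thresholding produced an empty foreground."""


@dataclass(frozen=True)
class SegmentedRegion:
    """Binary segmentation result: full foreground mask plus the selected
    focus region (largest 8-connected component)."""

    mask: np.ndarray           # full binarized foreground, bool HxW
    region_mask: np.ndarray    # selected focus component, bool HxW
    area_px: int               # AREA
    perimeter_px: float        # FRP
    threshold: int             # saturation threshold used (bin index)

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("region must be nonempty")
        if self.perimeter_px <= 0:
            raise ValueError("perimeter must be positive")
        if bool(np.any(self.region_mask & ~self.mask)):
            raise ValueError("region must be a subset of the foreground mask")

    @property
    def region_pixels(self) -> np.ndarray:
        """(row, col) coordinates of the focus region, 0-based row-major."""
        return np.argwhere(self.region_mask)


@dataclass(frozen=True)
class FeatureVector:
    """MD / ED / WPD plus the intermediates they are computed from."""

    MD: float
    ED: float
    WPD: float
    EFP: float
    area: int = 0
    perimeter: float = 0.0
    fallback: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.MD, self.ED, self.WPD], dtype=float)


@dataclass(frozen=True)
class FeatureScaler:
    """Min/max of the focus area over the training regions (AREA_min, AREA_max)."""

    area_min: float
    area_max: float

    def __post_init__(self) -> None:
        if self.area_min <= 0 or self.area_max <= 0:
            raise ValueError("areas must be positive")
        if self.area_min > self.area_max:
            raise ValueError("area_min must be <= area_max")

    def weight(self, area: float) -> float:
        """Min-max area weight, clamped to [0, 1]; 0 when degenerate."""
        if self.area_max == self.area_min:
            return 0.0
        return float(np.clip((area - self.area_min)
                             / (self.area_max - self.area_min), 0.0, 1.0))


def otsu_threshold(histogram: np.ndarray) -> int:
    """Discriminant-analysis (Otsu) threshold of a 256-bin histogram.

    Returns the bin index t maximizing the between-class variance of the
    split (<= t, > t); ties are broken by the lowest index.  Raises
    :class:`DegenerateImageError` when fewer than two bins are occupied.
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if (h < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    if np.count_nonzero(h) < 2:
        raise DegenerateImageError("degenerate image: single-valued histogram")
    total = h.sum()
    bins = np.arange(256, dtype=float)
    w0 = np.cumsum(h)                       # mass of class <= t
    m0 = np.cumsum(h * bins)                # first moment of class <= t
    mu_total = m0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(256)
    mu0 = np.where(w0 > 0, m0 / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (mu_total - m0) / np.maximum(w1, 1), 0.0)
    sigma_b[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    return int(np.argmax(sigma_b))          # argmax returns the first maximum


def saturation_histogram(image: FocusImage | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """HSV saturation quantized to [0, 255] integers, and its 256-bin histogram."""
    px = image.pixels if isinstance(image, FocusImage) else np.asarray(image)
    sat = rgb2hsv(px)[:, :, 1]
    sat_q = np.round(sat * 255).astype(np.int64)
    hist = np.bincount(sat_q.ravel(), minlength=256)[:256]
    return sat_q, hist


def segment_focus(image: FocusImage | np.ndarray) -> SegmentedRegion:
    """Binarize by Otsu on HSV saturation; keep the largest 8-connected
    component as the focus region.

    Foreground is saturation strictly above the threshold (the threshold bin
    belongs to the background class of the discriminant split).
    """
    sat_q, hist = saturation_histogram(image)
    t = otsu_threshold(hist)
    fg = sat_q > t
    if not fg.any():
        raise NoFocusRegionError("no focus region: empty foreground after thresholding")
    labels, n = cc_label(fg, connectivity=2, return_num=True)
    if n == 0:
        raise NoFocusRegionError("no focus region: empty foreground after thresholding")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))
    region = labels == best
    area = int(region.sum())
    perim = float(region_perimeter(region, neighborhood=4))
    if perim <= 0:  # single-pixel or degenerate region: fall back to crack length
        perim = 4.0
    return SegmentedRegion(mask=fg, region_mask=region, area_px=area,
                           perimeter_px=perim, threshold=t)


def to_grayscale(px: np.ndarray) -> np.ndarray:
    """Rec. 601 luma, rounded to integer (0-255)."""
    f = px.astype(float)
    return np.round(0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2])


def compute_features(region: SegmentedRegion, gray_image: np.ndarray,
                     scaler: FeatureScaler) -> FeatureVector:
    """MD / ED / WPD for one segmented region.

    MD is the median gray value over the region; ED and EFP follow in closed
    form from the area; WPD applies the min-max area weight (clamped to
    [0, 1]; defined as 0 when the scaler is degenerate).
    """
    gray = np.asarray(gray_image)
    if gray.shape != region.region_mask.shape:
        raise ValueError("gray image and region mask shapes differ")
    area = float(region.area_px)
    md = float(np.median(gray[region.region_mask]))
    ed = float(np.sqrt(4.0 * area / np.pi))
    efp = float(np.pi * ed)
    wpd = (region.perimeter_px - efp) * scaler.weight(area)
    return FeatureVector(MD=md, ED=ed, WPD=float(wpd), EFP=efp,
                         area=region.area_px, perimeter=region.perimeter_px)


def fallback_features(gray_image: np.ndarray) -> FeatureVector:
    """Feature vector assigned when no focus region segments out.

    MD is the whole-image (background) median; ED and WPD are zero; the
    fallback flag is set so batch runs can audit these rows.
    """
    md = float(np.median(np.asarray(gray_image)))
    return FeatureVector(MD=md, ED=0.0, WPD=0.0, EFP=0.0, area=0,
                         perimeter=0.0, fallback=True)


def fit_scaler(training_regions: list[SegmentedRegion],
               allow_degenerate: bool = True) -> FeatureScaler:
    """AREA_min / AREA_max over the training regions.

    All-equal areas yield a degenerate scaler whose weight is defined as 0
    (or an error when ``allow_degenerate`` is off).
    """
    if len(training_regions) < 2:
        raise ValueError("need at least 2 training regions")
    areas = [r.area_px for r in training_regions]
    amin, amax = float(min(areas)), float(max(areas))
    if amin == amax and not allow_degenerate:
        raise ValueError("all training areas equal: area weight undefined")
    return FeatureScaler(area_min=amin, area_max=amax)


def extract_batch(manifest: DatasetManifest, scaler: FeatureScaler | None = None,
                  out_csv: str | Path | None = None) -> tuple[pd.DataFrame, FeatureScaler]:
    """Segment every manifest image and compute its feature vector.

    When ``scaler`` is None it is fitted on the non-fallback regions of this
    batch (training usage); pass a fitted scaler for held-out data.  Output
    columns: ``id,label,MD,ED,WPD,area,perimeter,threshold,fallback_flag``.
    """
    images = images_for(manifest)
    regions: list[SegmentedRegion | None] = []
    grays = []
    for img in images:
        grays.append(to_grayscale(img.pixels))
        try:
            regions.append(segment_focus(img))
        except (DegenerateImageError, NoFocusRegionError):
            regions.append(None)
    if scaler is None:
        usable = [r for r in regions if r is not None]
        if len(usable) < 2:
            raise ValueError("cannot fit scaler: fewer than 2 segmentable images")
        scaler = fit_scaler(usable)
    rows = []
    for img, region, gray in zip(images, regions, grays):
        if region is None:
            fv = fallback_features(gray)
            thr = -1
        else:
            fv = compute_features(region, gray, scaler)
            thr = region.threshold
        rows.append({"id": img.id, "label": img.label, "MD": fv.MD, "ED": fv.ED,
                     "WPD": fv.WPD, "area": fv.area, "perimeter": fv.perimeter,
                     "threshold": thr, "fallback_flag": int(fv.fallback)})
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df, scaler
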