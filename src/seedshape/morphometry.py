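"""Plate segmentation and the seven classical morphometric descriptors.

Descriptors, all in physical units via the mm-per-pixel calibration:

======  ==============================================================
A       area, foreground pixel count x scale^2 (mm^2)
P       perimeter, smoothed sub-pixel contour polygon length (mm)
L, W    major / minor axis of the moment-equivalent ellipse (mm)
AR      aspect ratio L / W (>= 1)
C       circularity 4 pi A / P^2 (1 for a disk, lower for rough outlines)
R       roundness 4 A / (pi L^2) (insensitive to boundary roughness)
======  ==============================================================

Circularity therefore penalizes boundary irregularity (which inflates P)
while roundness only responds to elongation — the distinction that makes the
two useful side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .silhouette import BinarySilhouette, contour_perimeter, crop_mask, orient_mask

__all__ = [
    "SegmentationConfig",
    "SegmentationReport",
    "MorphometricRecord",
    "segment_plate",
    "orient_silhouette",
    "measure",
    "measure_population",
    "summarize_population",
    "cv_percent",
]

MORPHO_COLUMNS = ["label", "view", "A_mm2", "P_mm", "L_mm", "W_mm", "AR", "C", "R"]


@dataclass
class SegmentationConfig:
    """How to binarize and filter a plate image.

    ``polarity`` says whether seeds are darker or lighter than the
    background; ``min_area_px`` discards dust and specks.
    """

    scale_mm_per_px: float
    polarity: str = "dark"  # seeds darker than background
    min_area_px: int = 100
    view: str = "lateral"

    def __post_init__(self) -> None:
        if self.scale_mm_per_px is None or self.scale_mm_per_px <= 0:
            raise ValueError("calibration missing: scale_mm_per_px must be > 0")
        if self.polarity not in ("dark", "light"):
            raise ValueError("polarity must be 'dark' or 'light'")


@dataclass
class SegmentationReport:
    n_kept: int = 0
    n_border_rejected: int = 0
    n_small_rejected: int = 0


@dataclass
class MorphometricRecord:
    """Per-seed descriptors; see the module docstring for definitions."""

    label: str
    view: str
    A: float
    P: float
    L: float
    W: float
    AR: float
    C: float
    R: float


def _load_gray(image) -> np.ndarray:
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        return np.asarray(Image.open(image).convert("L"), dtype=float)
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return arr


def segment_plate(
    image, cfg: SegmentationConfig
) -> tuple[list[BinarySilhouette], SegmentationReport]:
    """Extract one binary silhouette per seed from a plate photograph.

    Otsu binarization with the configured polarity, 8-connected labeling,
    then filtering: components smaller than ``min_area_px`` and components
    touching the image border are discarded (the latter cannot be measured
    whole) and counted in the report. Kept silhouettes are cropped with a
    2-px margin and labeled ``seed_000``, ``seed_001``, ... in row-major
    order of their centroids.
    """
    arr = _load_gray(image)
    if arr.max() - arr.min() < 1:
        raise ValueError("no objects found: image has fewer than 2 gray levels")
    thr = threshold_otsu(arr)
    fg = arr < thr if cfg.polarity == "dark" else arr > thr

    labels, ncomp = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if ncomp == 0:
        raise ValueError("no objects found")
    report = SegmentationReport()
    silhouettes: list[BinarySilhouette] = []
    order = []
    for region in regionprops(labels):
        if region.area < cfg.min_area_px:
            report.n_small_rejected += 1
            continue
        minr, minc, maxr, maxc = region.bbox
        if minr == 0 or minc == 0 or maxr == labels.shape[0] or maxc == labels.shape[1]:
            report.n_border_rejected += 1
            continue
        order.append((region.centroid, region.label))
    if not order and report.n_border_rejected == 0:
        raise ValueError("no objects found")
    order.sort()
    for i, (_, lab) in enumerate(order):
        mask = crop_mask(labels == lab, 2)
        silhouettes.append(
            BinarySilhouette(
                mask,
                scale_mm_per_px=cfg.scale_mm_per_px,
                label=f"seed_{i:03d}",
                view=cfg.view,
            )
        )
    report.n_kept = len(silhouettes)
    return silhouettes, report


def orient_silhouette(s: BinarySilhouette) -> BinarySilhouette:
    """Rotate the symmetry axis horizontal, hilum notch to the right.

    The silhouette's ``view`` selects the orientation convention: lateral
    profiles have a single mirror-symmetry axis, dorsal profiles two (and
    are kept wider than tall).
    """
    return s.with_mask(orient_mask(s.mask, two_axis=(s.view == "dorsal")))


def measure(s: BinarySilhouette, smooth_window: int = 5) -> MorphometricRecord:
    """Compute A, P, L, W, AR, C, R for one silhouette in physical units."""
    if s.area_px < 16:
        raise ValueError("degenerate component (fewer than 16 foreground pixels)")
    scale = s.scale_mm_per_px
    area = s.area_px * scale**2
    perim = contour_perimeter(s.mask, smooth_window) * scale
    props = regionprops(s.mask.astype(np.uint8))[0]
    major = props.axis_major_length * scale
    minor = props.axis_minor_length * scale
    if minor <= 0:
        raise ValueError("degenerate component: zero minor axis")
    return MorphometricRecord(
        label=s.label,
        view=s.view,
        A=area,
        P=perim,
        L=major,
        W=minor,
        AR=major / minor,
        C=4.0 * np.pi * area / perim**2,
        R=4.0 * area / (np.pi * major**2),
    )


def measure_population(
    silhouettes: list[BinarySilhouette], smooth_window: int = 5
) -> pd.DataFrame:
    """Per-seed morphometry table with the fixed output column schema."""
    rows = []
    for s in silhouettes:
        rec = measure(s, smooth_window)
        rows.append(
            {
                "label": rec.label,
                "view": rec.view,
                "A_mm2": rec.A,
                "P_mm": rec.P,
                "L_mm": rec.L,
                "W_mm": rec.W,
                "AR": rec.AR,
                "C": rec.C,
                "R": rec.R,
            }
        )
    return pd.DataFrame(rows, columns=MORPHO_COLUMNS)


def cv_percent(values) -> float:
    """Coefficient of variation, percent scale, sample SD (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires n >= 2")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean: corrupt input for a strictly positive trait")
    return float(v.std(ddof=1) / mean * 100.0)


def summarize_population(records) -> pd.DataFrame:
    """Per-trait mean, sample SD and CV (%) over a population.

    ``records`` is a list of :class:`MorphometricRecord` or a DataFrame in
    the :data:`MORPHO_COLUMNS` schema.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        traits = [c for c in df.columns if c not in ("label", "view")]
    else:
        if len(records) < 2:
            raise ValueError("summary requires n >= 2")
        df = pd.DataFrame(
            [
                {"A_mm2": r.A, "P_mm": r.P, "L_mm": r.L, "W_mm": r.W,
                 "AR": r.AR, "C": r.C, "R": r.R}
                for r in records
            ]
        )
        traits = list(df.columns)
    if len(df) < 2:
        raise ValueError("summary requires n >= 2")
    out = pd.DataFrame(
        {
            "mean": df[traits].mean(),
            "sd": df[traits].std(ddof=1),
        }
    )
    out["cv"] = [cv_percent(df[t]) for t in traits]
    out.index.name = "trait"
    return out
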