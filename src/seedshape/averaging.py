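"""Average silhouettes via per-pixel occupancy maps.

The representative shape of a seed population is built by stacking aligned
binary masks and keeping the region covered by at least a threshold fraction
``tau`` of the seeds. Stacking N translucent layers of equal opacity and
looking for "the darkest area" is, mathematically, exactly this per-pixel
coverage fraction, so the occupancy map is the transparent replacement for
the manual layer-opacity protocol: ``tau = 1`` gives the intersection of all
seeds, ``tau -> 0`` their union, and the default ``tau = 0.8`` the region
where most seeds coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import transform

from .silhouette import BinarySilhouette, crop_mask

__all__ = ["OccupancyMap", "build_occupancy", "average_silhouette"]


@dataclass
class OccupancyMap:
    """Per-pixel fraction of seeds covering each pixel, in [0, 1]."""

    values: np.ndarray
    n_seeds: int
    scale_mm_per_px: float = 1.0

    def to_png(self, path) -> None:
        """Write as a 16-bit grayscale PNG for inspection."""
        arr = np.round(self.values * 65535).astype(np.uint16)
        Image.fromarray(arr).save(path)


def build_occupancy(
    seeds: list[BinarySilhouette],
    align: str = "centroid",
    scale_normalize: bool = True,
) -> OccupancyMap:
    """Stack silhouettes into a coverage-fraction map.

    With ``align="centroid"`` (default) every silhouette is translated so its
    centroid sits at the canvas center, and with ``scale_normalize`` each is
    first rescaled to the population's mean equivalent-circle radius, so the
    population's size spread does not erode the average's boundary. With
    ``align="none"`` masks are stacked as given on a common canvas anchored
    at their top-left corner (they must then already live on a shared grid).
    """
    if not seeds:
        raise ValueError("empty input list")
    if align not in ("centroid", "none"):
        raise ValueError("align must be 'centroid' or 'none'")
    n = len(seeds)

    masks = [s.mask for s in seeds]
    if scale_normalize and align == "centroid":
        radii = [s.equivalent_radius_px for s in seeds]
        target = float(np.mean(radii))
        rescaled = []
        for m, r in zip(masks, radii):
            f = target / r
            if abs(f - 1.0) < 1e-9:
                rescaled.append(m)
            else:
                rescaled.append(transform.rescale(m.astype(float), f, order=1) > 0.5)
        masks = rescaled

    if align == "none":
        h = max(m.shape[0] for m in masks)
        w = max(m.shape[1] for m in masks)
        acc = np.zeros((h, w), dtype=np.int32)
        for m in masks:
            acc[: m.shape[0], : m.shape[1]] += m
    else:
        h = max(m.shape[0] for m in masks)
        w = max(m.shape[1] for m in masks)
        h, w = int(h * 1.5) + 4, int(w * 1.5) + 4
        acc = np.zeros((h, w), dtype=np.int32)
        for m in masks:
            rr, cc = np.nonzero(m)
            dr = int(round(h / 2 - rr.mean()))
            dc = int(round(w / 2 - cc.mean()))
            acc[rr + dr, cc + dc] += 1

    return OccupancyMap(acc / n, n_seeds=n, scale_mm_per_px=seeds[0].scale_mm_per_px)


def average_silhouette(
    occ: OccupancyMap, tau: float = 0.8, label: str = "average", view: str = "lateral"
) -> BinarySilhouette:
    """Threshold the occupancy map at coverage ``tau`` (largest component).

    ``tau`` in (0, 1]: a pixel is foreground when at least a fraction tau of
    the seeds cover it. Speckle from ties at the threshold is resolved by
    keeping the largest 8-connected component.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    fg = occ.values >= tau - 1e-9
    if not fg.any():
        raise ValueError("threshold yields empty foreground")
    labels, ncomp = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if ncomp > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, ncomp + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    return BinarySilhouette(
        crop_mask(fg, 2), scale_mm_per_px=occ.scale_mm_per_px, label=label, view=view
    )
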