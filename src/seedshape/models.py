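"""Parametric geometric reference shapes for seed-silhouette comparison.

Two families cover the two photographic views of a seed:

* **LM (lateral models)** — a cardioid family. The base curve is the cardioid
  ``r(theta) = a (1 + cos theta)`` whose cusp forms the hilum notch. Named
  variants are produced by four documented modifiers:

  - ``flatten``   — vertical scale factor (< 1 flattens the profile);
  - ``elongate``  — horizontal scale factor (> 1 elongates it);
  - ``notch_open``— blends the cusp toward an open (limaçon-like) curve:
    ``r = a [(1 - v)(1 + cos t) + v]``, v in [0, 1);
  - ``hilum``     — multiplies the radius by a smooth cosine-squared bump
    inside an angular window around the cusp, filling (h > 0) or deepening
    (h < 0) the hilum region.

* **DM (dorsal models)** — super-ellipses (Lamé curves)
  ``|x/a|^n + |y/b|^n = 1``; ``n = 2`` is an exact ellipse, larger ``n``
  approaches the bounding rectangle.

Canonical orientation everywhere: symmetry axis horizontal, hilum notch on
the right. Models may also be loaded from binary raster images (the form in
which published model silhouettes are distributed); such models carry their
extracted boundary polygon instead of a parametric curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage
from scipy.special import gamma

from .silhouette import (
    BinarySilhouette,
    contour_polygon,
    crop_mask,
    fill_polygon,
    orient_mask,
)

__all__ = [
    "GeometricModel",
    "make_model",
    "rasterize_model",
    "load_model_image",
    "model_presets",
    "LM_MODELS",
    "DM_MODELS",
]

LM_MODELS = tuple(f"LM{i}" for i in range(1, 9))
DM_MODELS = ("DM1", "DM5", "DM6")

_HILUM_WINDOW = 0.9  # radians on each side of theta = pi


def model_presets() -> dict[str, dict]:
    """The named model_id -> parameter presets shipped with the package."""
    text = resources.files("seedshape").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class GeometricModel:
    """A named reference shape in canonical orientation.

    ``source`` is ``"parametric"`` for family members and ``"raster"`` for
    shapes loaded from an image; raster models store their boundary in
    ``_polygon`` directly. ``polygon()`` returns the boundary for either
    source on a common convention: (row, col) image coordinates, centroid at
    the origin, normalized to unit area — the form the registration stage
    transforms and rasterizes.
    """

    model_id: str
    source: str = "parametric"
    params: dict = field(default_factory=dict)
    _polygon: np.ndarray | None = None  # raster-sourced boundary, normalized

    # -- parametric curves --------------------------------------------------
    @property
    def family(self) -> str:
        if self.source == "raster":
            return "raster"
        return "LM" if "b" not in self.params else "DM"

    def radius(self, theta: np.ndarray) -> np.ndarray:
        """Polar radius of the defining curve.

        For the LM family the pole is the cardioid cusp; for the DM family it
        is the center of the super-ellipse. Raster models have no closed-form
        radius.
        """
        theta = np.asarray(theta, dtype=float)
        p = self.params
        if self.family == "LM":
            a = p["a"]
            v = p.get("notch_open", 0.0)
            h = p.get("hilum", 0.0)
            r = a * ((1.0 - v) * (1.0 + np.cos(theta)) + v)
            if h:
                d = np.abs((theta - np.pi) % (2 * np.pi))
                d = np.minimum(d, 2 * np.pi - d)
                bump = np.where(
                    d < _HILUM_WINDOW,
                    np.cos(0.5 * np.pi * d / _HILUM_WINDOW) ** 2,
                    0.0,
                )
                r = r * (1.0 + h * bump)
            return r
        if self.family == "DM":
            a, b, n = p["a"], p["b"], p["n"]
            return (
                np.abs(np.cos(theta) / a) ** n + np.abs(np.sin(theta) / b) ** n
            ) ** (-1.0 / n)
        raise ValueError("raster-sourced model has no parametric radius")

    def boundary_xy(self, n: int = 720) -> np.ndarray:
        """Closed boundary in math (x, y) coordinates, canonical orientation.

        For LM models the curve is mirrored so the cusp/notch sits at +x; the
        anisotropic flatten/elongate factors are applied here.
        """
        if self.source == "raster":
            raise ValueError("raster model: use polygon()")
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        r = self.radius(theta)
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        if self.family == "LM":
            e = self.params.get("elongate", 1.0)
            f = self.params.get("flatten", 1.0)
            x = -x * e  # mirror: cusp (theta = pi) to the right
            y = y * f
        return np.column_stack([x, y])

    # -- common polygon convention -----------------------------------------
    def polygon(self, n: int = 720) -> np.ndarray:
        """Boundary as (row, col) vertices, centroid at origin, unit area."""
        if self.source == "raster":
            return self._polygon
        xy = self.boundary_xy(n)
        rc = np.column_stack([-xy[:, 1], xy[:, 0]])  # y up -> row down
        return _normalize_polygon(rc)

    def unit_area_scale(self) -> float:
        """Pixels-per-unit linear scale s such that area(s * polygon) = s**2."""
        return 1.0  # polygon() is already unit-area

    def __repr__(self) -> str:  # params dict is noisy
        return f"GeometricModel({self.model_id!r}, source={self.source!r})"


def _polygon_area_centroid(rc: np.ndarray) -> tuple[float, np.ndarray]:
    r0, c0 = rc[:, 0], rc[:, 1]
    r1, c1 = np.roll(r0, -1), np.roll(c0, -1)
    cross = c0 * r1 - c1 * r0
    area = 0.5 * cross.sum()
    cr = ((r0 + r1) * cross).sum() / (6.0 * area)
    cc = ((c0 + c1) * cross).sum() / (6.0 * area)
    return abs(area), np.array([cr, cc])


def _normalize_polygon(rc: np.ndarray) -> np.ndarray:
    area, cen = _polygon_area_centroid(rc)
    if area <= 0:
        raise ValueError("degenerate (zero-area) curve")
    return (rc - cen) / math.sqrt(area)


def make_model(model_id: str, **params) -> GeometricModel:
    """Create a parametric model from a named preset or custom parameters.

    ``model_id`` is one of LM1..LM8, DM1, DM5, DM6 (preset parameters, which
    explicit keyword arguments override) or ``"custom"`` with explicit
    parameters (``a`` plus LM modifiers, or ``a``, ``b``, ``n`` for a
    super-ellipse).
    """
    presets = model_presets()
    if model_id in presets:
        merged = {**presets[model_id], **params}
    elif model_id == "custom":
        if not params:
            raise ValueError("custom model requires explicit parameters")
        merged = dict(params)
    else:
        raise ValueError(f"unknown model_id {model_id!r}")

    if merged.get("a", 0) <= 0 or merged.get("b", 1) <= 0:
        raise ValueError("model scale parameters must be positive")
    if "n" in merged and merged["n"] < 1:
        raise ValueError("super-ellipse exponent n must be >= 1")
    if merged.get("notch_open", 0.0) >= 1.0 or merged.get("hilum", 0.0) <= -1.0:
        raise ValueError("parameters produce a degenerate curve")
    model = GeometricModel(model_id=model_id, source="parametric", params=merged)
    # reject curves that collapse (e.g. extreme flatten)
    if _polygon_area_centroid(
        np.column_stack([-model.boundary_xy()[:, 1], model.boundary_xy()[:, 0]])
    )[0] <= 1e-9:
        raise ValueError("parameters produce a degenerate curve")
    return model


def superellipse_area(a: float, b: float, n: float) -> float:
    """Closed-form area of |x/a|^n + |y/b|^n = 1 (Gamma-function formula)."""
    return 4.0 * a * b * gamma(1 + 1 / n) ** 2 / gamma(1 + 2 / n)


def rasterize_model(
    model: GeometricModel, height_px: int = 400, n_boundary: int = 720
) -> BinarySilhouette:
    """Render a model as a binary silhouette of the given pixel height.

    The boundary polygon is scaled so its vertical extent equals
    ``height_px``, then filled with the even-odd pixel-center rule and
    cropped with a 2-px margin.
    """
    if height_px < 16:
        raise ValueError("height_px must be >= 16")
    poly = model.polygon(n_boundary)
    r_ext = poly[:, 0].max() - poly[:, 0].min()
    s = height_px / r_ext
    scaled = poly * s
    offset = scaled.min(axis=0)
    scaled = scaled - offset + 2.0
    h = int(np.ceil(scaled[:, 0].max())) + 3
    w = int(np.ceil(scaled[:, 1].max())) + 3
    mask = fill_polygon(scaled, (h, w))
    if mask.sum() == 0:
        raise ValueError("rasterization produced an empty mask")
    rr, cc = np.nonzero(mask)
    if rr.max() == rr.min() or cc.max() == cc.min():
        raise ValueError("height too small to resolve the model")
    _, ncomp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if ncomp != 1:
        raise ValueError("rasterization produced multiple components")
    return BinarySilhouette(
        crop_mask(mask, 2), label=model.model_id,
        view="lateral" if model.family == "LM" else "dorsal",
    )


def load_model_image(
    path, smooth_window: int = 5, view: str | None = None
) -> GeometricModel:
    """Load a model silhouette from a raster image file.

    The image is converted to grayscale and binarized with Otsu's threshold;
    polarity (shape drawn dark-on-light or light-on-dark) is detected by
    taking the class prevailing on the image border as background. The mask
    is normalized to canonical orientation (symmetry axis horizontal, notch
    right) and its smoothed sub-pixel boundary becomes the model polygon.
    Pass ``view`` (``"lateral"`` or ``"dorsal"``) to pin the orientation
    convention; by default it is inferred from the mirror symmetry of the
    outline.
    """
    from PIL import Image
    from skimage.filters import threshold_otsu

    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    if arr.max() - arr.min() < 1:
        raise ValueError("blank image")
    fg = arr > threshold_otsu(arr)
    border = np.concatenate([fg[0], fg[-1], fg[:, 0], fg[:, -1]])
    if border.mean() > 0.5:  # light border -> shape is the dark class
        fg = ~fg
    labels, ncomp = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, ncomp + 1))
    big = np.flatnonzero(sizes >= 8) + 1
    if big.size == 0:
        raise ValueError("blank image")
    if big.size > 1:
        raise ValueError("multiple components")
    if view is not None and view not in ("lateral", "dorsal"):
        raise ValueError("view must be 'lateral' or 'dorsal'")
    two_axis = None if view is None else (view == "dorsal")
    mask = orient_mask(labels == big[0], two_axis=two_axis)
    poly = _normalize_polygon(contour_polygon(mask, smooth_window))
    return GeometricModel(
        model_id="custom", source="raster", params={"path": str(path)},
        _polygon=poly,
    )
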