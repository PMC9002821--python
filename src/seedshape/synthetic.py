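"""Synthetic seed silhouettes, populations and plate images.

The generator emulates the study material the pipeline was designed for:
populations of seed-like shapes derived from a known geometric base model
(a cardioid-family lateral model or a super-ellipse dorsal model), each seed
perturbed by smooth low-order radial harmonics, drawn at a lognormally
distributed size, and optionally laid out on a photographic plate (dark
seeds on a light background with pixel noise). Every planted parameter is
returned as ground truth, so segmentation, measurement, averaging,
registration and the group statistics can all be validated end to end
without any external data.

The boundary of a synthetic seed is

    r(theta) = r_model(theta) * (1 + sum_k a_k cos(k theta) + b_k sin(k theta))

with harmonics k in a low-order band (default 2-8) and coefficients drawn
i.i.d. Gaussian with SD = noise_amplitude / sqrt(n_harmonics), which makes
``noise_amplitude`` the RMS relative boundary perturbation. Realizations
whose multiplier comes close to zero anywhere (a self-intersecting outline)
are rejected and resampled with a retry cap. All randomness flows from one
explicit seed; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import GeometricModel, make_model
from .silhouette import BinarySilhouette, crop_mask, fill_polygon

__all__ = ["SyntheticSpec", "generate_seed", "generate_population", "generate_plate"]


@dataclass
class SyntheticSpec:
    """Ground-truth recipe for a synthetic seed population.

    ``noise_amplitude`` is the RMS radial perturbation as a fraction of the
    local radius (0.02 = 2%); ``size_cv`` the percent coefficient of
    variation of the linear scale across seeds; ``height_px`` the nominal
    rasterized seed height; ``rotation_jitter_deg`` a uniform rotation range
    applied on plates (individual seeds are generated in canonical
    orientation, like the aligned composed images the pipeline targets).
    """

    base_model: GeometricModel | str = "LM1"
    n_seeds: int = 20
    noise_amplitude: float = 0.02
    noise_harmonics: tuple[int, int] = (2, 8)
    size_cv: float = 10.0
    height_px: int = 240
    rotation_jitter_deg: float = 0.0
    plate_size: tuple[int, int] | None = None
    rng_seed: int = 0
    n_boundary: int = 720
    max_retries: int = 20

    def __post_init__(self) -> None:
        if isinstance(self.base_model, str):
            self.base_model = make_model(self.base_model)
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


def _noisy_polygon(spec: SyntheticSpec, rng: np.random.Generator):
    """Unit-area (row, col) polygon of one perturbed seed + noise record."""
    model = spec.base_model
    theta = np.linspace(0.0, 2 * np.pi, spec.n_boundary, endpoint=False)
    k_lo, k_hi = spec.noise_harmonics
    ks = np.arange(k_lo, k_hi + 1)
    sd = spec.noise_amplitude / np.sqrt(len(ks)) if len(ks) else 0.0
    for _ in range(spec.max_retries):
        a = rng.normal(0.0, sd, len(ks))
        b = rng.normal(0.0, sd, len(ks))
        factor = 1.0 + (
            a @ np.cos(np.outer(ks, theta)) + b @ np.sin(np.outer(ks, theta))
        )
        if factor.min() > 0.05:
            break
    else:
        raise ValueError("noise too large: boundary self-intersects repeatedly")

    r = model.radius(theta) * factor
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    if model.family == "LM":
        x = -x * model.params.get("elongate", 1.0)
        y = y * model.params.get("flatten", 1.0)
    rc = np.column_stack([-y, x])
    # normalize exactly as GeometricModel.polygon does
    from .models import _normalize_polygon

    return _normalize_polygon(rc), {"coef_a": a, "coef_b": b}


def _polygon_scale_for_height(model: GeometricModel, height_px: int) -> float:
    poly = model.polygon()
    return height_px / (poly[:, 0].max() - poly[:, 0].min())


def _rasterize_polygon(
    poly: np.ndarray, s: float, theta_rad: float = 0.0
) -> np.ndarray:
    v = poly * s
    if theta_rad:
        ct, st = np.cos(theta_rad), np.sin(theta_rad)
        v = v @ np.array([[ct, st], [-st, ct]]).T
    v = v - v.min(axis=0) + 2.0
    h = int(np.ceil(v[:, 0].max())) + 3
    w = int(np.ceil(v[:, 1].max())) + 3
    return crop_mask(fill_polygon(v, (h, w)), 2)


def generate_seed(
    spec: SyntheticSpec, rng: np.random.Generator | None = None, index: int = 0
) -> tuple[BinarySilhouette, dict]:
    """One synthetic seed in canonical orientation plus its ground truth.

    The truth record stores the planted polygon scale ``s_px`` (pixels per
    unit-area model polygon — directly comparable to the scale recovered by
    the registration search), the relative size factor, and the noise
    realization.
    """
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    poly, noise = _noisy_polygon(spec, rng)
    base_s = _polygon_scale_for_height(spec.base_model, spec.height_px)
    if spec.size_cv > 0 and spec.n_seeds > 0:
        cv = spec.size_cv / 100.0
        sigma = np.sqrt(np.log1p(cv**2))
        size_factor = float(rng.lognormal(-0.5 * sigma**2, sigma))
    else:
        size_factor = 1.0
    s_px = base_s * size_factor
    mask = _rasterize_polygon(poly, s_px)
    sil = BinarySilhouette(
        mask, label=f"synthetic_{index:03d}",
        view="lateral" if spec.base_model.family == "LM" else "dorsal",
    )
    truth = {
        "label": sil.label, "s_px": s_px, "size_factor": size_factor,
        "noise_amplitude": spec.noise_amplitude, **noise,
    }
    return sil, truth


def generate_population(
    spec: SyntheticSpec,
) -> tuple[list[BinarySilhouette], pd.DataFrame]:
    """A population of ``spec.n_seeds`` seeds and its planted-truth table."""
    rng = np.random.default_rng(spec.rng_seed)
    seeds, rows = [], []
    for i in range(spec.n_seeds):
        sil, truth = generate_seed(spec, rng, index=i)
        seeds.append(sil)
        rows.append(
            {k: v for k, v in truth.items() if not isinstance(v, np.ndarray)}
        )
    return seeds, pd.DataFrame(rows)


def generate_plate(
    spec: SyntheticSpec,
    background: float = 220.0,
    foreground: float = 40.0,
    pixel_noise_sd: float = 6.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A grayscale plate image of the population with known positions.

    Seeds (dark on light by default) are placed on a jittered grid, never
    overlapping and never touching the border; additive Gaussian pixel noise
    is applied and the image clipped to uint8. Returns the image and a
    table of planted centroids and sizes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    masks, rows = [], []
    for i in range(spec.n_seeds):
        poly, noise = _noisy_polygon(spec, rng)
        base_s = _polygon_scale_for_height(spec.base_model, spec.height_px)
        cv = spec.size_cv / 100.0
        sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
        size_factor = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma else 1.0
        theta = (
            np.radians(rng.uniform(-spec.rotation_jitter_deg, spec.rotation_jitter_deg))
            if spec.rotation_jitter_deg
            else 0.0
        )
        masks.append(_rasterize_polygon(poly, base_s * size_factor, theta))
        rows.append({"size_factor": size_factor, "theta_rad": theta})

    cell = max(max(m.shape) for m in masks) + 8
    n_cols = int(np.ceil(np.sqrt(spec.n_seeds)))
    n_rows = int(np.ceil(spec.n_seeds / n_cols))
    if spec.plate_size is not None:
        plate_h, plate_w = spec.plate_size
        if plate_h < n_rows * cell + 8 or plate_w < n_cols * cell + 8:
            raise ValueError("plate too small for non-overlapping placement")
    else:
        plate_h, plate_w = n_rows * cell + 8, n_cols * cell + 8

    img = np.full((plate_h, plate_w), background, dtype=float)
    for i, m in enumerate(masks):
        gr, gc = divmod(i, n_cols)
        slack_r = cell - m.shape[0]
        slack_c = cell - m.shape[1]
        jr = int(rng.integers(0, max(slack_r, 1)))
        jc = int(rng.integers(0, max(slack_c, 1)))
        r0 = 4 + gr * cell + jr
        c0 = 4 + gc * cell + jc
        img[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]][m] = foreground
        rr, cc = np.nonzero(m)
        rows[i].update(
            {
                "centroid_row": r0 + rr.mean(),
                "centroid_col": c0 + cc.mean(),
                "area_px": int(m.sum()),
            }
        )
    img = img + rng.normal(0.0, pixel_noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), pd.DataFrame(rows)
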