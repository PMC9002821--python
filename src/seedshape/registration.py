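"""J-index computation and silhouette-to-model registration.

The J index between two binary shapes is the percent area-overlap

    J = 100 * |S| / |T|

with S the shared (intersection) area and T the total (union) area — a
Jaccard similarity on the percent scale. It is 100 when the shapes coincide
and 0 when they are disjoint; values above 90 are conventionally read as a
good adjustment between a seed and a model.

Superimposing a model on a seed "with maximum adjustment" is automated here
as a similarity-transform optimization: the model's unit-area boundary
polygon is translated, scaled (and optionally rotated / mirrored /
anisotropically stretched) onto the seed's pixel grid, rasterized with the
package's even-odd fill rule, and the placement maximizing J is found with a
coarse-to-fine grid search followed by Nelder-Mead refinement. The search is
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from skimage import transform as sktransform

from .models import GeometricModel
from .morphometry import cv_percent
from .silhouette import BinarySilhouette, crop_mask, fill_polygon

__all__ = [
    "Placement",
    "JResult",
    "FitConfig",
    "j_index",
    "j_index_aligned",
    "fit_model",
    "render_fit",
    "j_table",
]


@dataclass(frozen=True)
class Placement:
    """A similarity placement of a model polygon on a seed's pixel grid.

    ``s`` is the isotropic scale applied to the unit-area model polygon (so
    the placed model's area is ``s**2`` pixels, times ``sy`` if anisotropy is
    enabled); ``tx``/``ty`` are column/row offsets in pixels from the seed
    centroid; ``theta`` is the rotation in radians; ``flip`` mirrors the
    model left-right before rotating.
    """

    tx: float = 0.0
    ty: float = 0.0
    s: float = 1.0
    theta: float = 0.0
    flip: bool = False
    sy: float = 1.0  # anisotropic width factor (columns), 1 = isotropic

    def __post_init__(self) -> None:
        if self.s <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")


@dataclass
class JResult:
    """Outcome of fitting one model to one silhouette."""

    model_id: str
    placement: Placement
    J: float
    S_area: int
    T_area: int


@dataclass
class FitConfig:
    """Search configuration for :func:`fit_model`.

    The default search optimizes translation and isotropic scale only —
    seeds are assumed pre-oriented, and the flattened/elongated model
    variants already encode anisotropy, so leaving rotation and stretch off
    keeps model identity meaningful. ``rotation_deg`` bounds an optional
    rotation dimension; ``standardize_height`` rescales the seed to a common
    height before fitting (placements are reported in native seed pixels).
    """

    rotation_deg: float = 0.0
    allow_flip: bool = False
    anisotropic: bool = False
    n_boundary: int = 720
    standardize_height: int | None = 400
    grid_levels: int = 3
    refine: bool = True
    margin_frac: float = 0.35


def j_index(a: np.ndarray, b: np.ndarray) -> float:
    """J index (percent Jaccard overlap) of two masks on a common grid."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid; composite them first")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both masks are empty")
    return 100.0 * np.logical_and(a, b).sum() / union


def j_index_aligned(a: BinarySilhouette, b: BinarySilhouette, height: int = 400) -> float:
    """J index after centroid alignment and equal-area scale normalization.

    Both silhouettes are rescaled so the first has the given pixel height
    and both have equal foreground area, then centered on a common canvas.
    A convenience for resolution-independence checks and quick comparisons;
    use :func:`fit_model` for the full placement optimization.
    """
    masks = []
    ha = np.ptp(np.nonzero(a.mask)[0]) + 1
    base = height / ha
    target_area = a.area_px * base**2
    for s in (a, b):
        f = np.sqrt(target_area / s.area_px)
        m = sktransform.rescale(s.mask.astype(float), f, order=1) > 0.5
        masks.append(m)
    h = max(m.shape[0] for m in masks) * 2
    w = max(m.shape[1] for m in masks) * 2
    grid = []
    for m in masks:
        canvas = np.zeros((h, w), dtype=bool)
        rr, cc = np.nonzero(m)
        dr = int(round(h / 2 - rr.mean()))
        dc = int(round(w / 2 - cc.mean()))
        canvas[rr + dr, cc + dc] = True
        grid.append(canvas)
    return j_index(grid[0], grid[1])


def _place_polygon(
    poly: np.ndarray, center_rc: tuple[float, float], p: Placement
) -> np.ndarray:
    v = poly
    if p.flip:
        v = v * np.array([1.0, -1.0])
    if p.sy != 1.0:
        v = v * np.array([1.0, p.sy])
    if p.theta != 0.0:
        ct, st = np.cos(p.theta), np.sin(p.theta)
        v = v @ np.array([[ct, st], [-st, ct]]).T
    v = v * p.s
    return v + np.array([center_rc[0] + p.ty, center_rc[1] + p.tx])


def _evaluate(poly, center, placement, seed_mask, seed_area) -> tuple[float, int, int]:
    # Fill only the model's bounding box; the union follows from the totals.
    verts = _place_polygon(poly, center, placement)
    h, w = seed_mask.shape
    rmin = max(int(np.floor(verts[:, 0].min())), 0)
    rmax = min(int(np.ceil(verts[:, 0].max())) + 1, h)
    cmin = max(int(np.floor(verts[:, 1].min())), 0)
    cmax = min(int(np.ceil(verts[:, 1].max())) + 1, w)
    if rmax <= rmin or cmax <= cmin:
        return 0.0, 0, int(seed_area)
    sub = fill_polygon(verts - np.array([rmin, cmin]), (rmax - rmin, cmax - cmin))
    model_area = int(sub.sum())
    inter = int(np.logical_and(sub, seed_mask[rmin:rmax, cmin:cmax]).sum())
    union = int(seed_area) + model_area - inter
    if union == 0:
        return 0.0, 0, 0
    return 100.0 * inter / union, inter, union


def fit_model(
    seed: BinarySilhouette, model: GeometricModel, cfg: FitConfig | None = None
) -> JResult:
    """Find the similarity placement of ``model`` maximizing J on ``seed``.

    The search is seeded analytically (model centroid on the seed centroid,
    model area equal to the seed area), explored with a three-level
    coarse-to-fine grid over (scale, translation) — plus rotation / flip /
    stretch dimensions when enabled — and polished with Nelder-Mead on the
    continuous parameters. The returned J never falls below the J of the
    analytic initial placement, and ties prefer the placement closest to it.
    """
    cfg = cfg or FitConfig()
    if seed.area_px == 0:
        raise ValueError("empty seed")
    work = crop_mask(seed.mask, 2)
    native_factor = 1.0
    if cfg.standardize_height:
        h = work.shape[0] - 4
        native_factor = cfg.standardize_height / h
        if abs(native_factor - 1.0) > 0.02:
            work = sktransform.rescale(work.astype(float), native_factor, order=1) > 0.5
        else:
            native_factor = 1.0
    margin = int(cfg.margin_frac * max(work.shape))
    work = np.pad(crop_mask(work, 2), margin)

    poly = model.polygon(cfg.n_boundary)
    if poly is None or len(poly) < 3:
        raise ValueError("model degenerate at required resolution")
    rr, cc = np.nonzero(work)
    center = (float(rr.mean()), float(cc.mean()))
    area = work.sum()
    s0 = float(np.sqrt(area))
    bbox_h = np.ptp(rr) + 1
    bbox_w = np.ptp(cc) + 1

    x0 = Placement(s=s0)
    best_j, best_inter, best_union = _evaluate(poly, center, x0, work, area)
    best_p = x0
    init_j = best_j

    def dist(p: Placement) -> float:
        return (
            (np.log(p.s / s0)) ** 2
            + (p.tx / bbox_w) ** 2
            + (p.ty / bbox_h) ** 2
            + p.theta**2
            + (np.log(p.sy)) ** 2
        )

    def consider(p: Placement) -> float:
        nonlocal best_j, best_p, best_inter, best_union
        j, inter, union = _evaluate(poly, center, p, work, area)
        if j > best_j or (j == best_j and dist(p) < dist(best_p)):
            best_j, best_p, best_inter, best_union = j, p, inter, union
        return j

    rot_bound = np.radians(cfg.rotation_deg)
    flips = (False, True) if cfg.allow_flip else (False,)

    # coarse-to-fine grids
    log_s_step = np.log(1.25 / 0.8) / 4
    steps = {
        "ls": log_s_step,
        "ty": 0.10 * bbox_h,
        "tx": 0.10 * bbox_w,
        "theta": rot_bound / 2 if rot_bound else 0.0,
        "lsy": np.log(1.2) / 2 if cfg.anisotropic else 0.0,
    }
    for level in range(cfg.grid_levels):
        if level == 0:
            offs = np.arange(-2, 3)
            c = {"ls": 0.0, "ty": 0.0, "tx": 0.0, "theta": 0.0, "lsy": 0.0}
        else:
            offs = np.arange(-1, 2) * 0.6
            c = {
                "ls": np.log(best_p.s / s0),
                "ty": best_p.ty,
                "tx": best_p.tx,
                "theta": best_p.theta,
                "lsy": np.log(best_p.sy),
            }
        th_vals = (
            np.clip(c["theta"] + offs * steps["theta"], -rot_bound, rot_bound)
            if rot_bound
            else np.array([0.0])
        )
        sy_vals = (
            np.exp(c["lsy"] + offs * steps["lsy"]) if cfg.anisotropic else np.array([1.0])
        )
        for flip in flips if level == 0 else (best_p.flip,):
            for ls in c["ls"] + offs * steps["ls"]:
                for ty in c["ty"] + offs * steps["ty"]:
                    for tx in c["tx"] + offs * steps["tx"]:
                        for th in np.unique(th_vals):
                            for sy in np.unique(sy_vals):
                                consider(
                                    Placement(
                                        tx=tx, ty=ty, s=s0 * np.exp(ls),
                                        theta=th, flip=flip, sy=sy,
                                    )
                                )
        for k in steps:
            steps[k] *= 0.6 if level == 0 else 0.6

    if cfg.refine:
        dims = ["ls", "ty", "tx"]
        if rot_bound:
            dims.append("theta")
        if cfg.anisotropic:
            dims.append("lsy")
        span = {"ls": 0.01, "ty": 1.0, "tx": 1.0, "theta": 0.01, "lsy": 0.01}

        def unpack(x) -> Placement:
            d = dict(zip(dims, x))
            th = d.get("theta", best_p.theta)
            if rot_bound:
                th = float(np.clip(th, -rot_bound, rot_bound))
            return Placement(
                tx=d.get("tx", best_p.tx),
                ty=d.get("ty", best_p.ty),
                s=s0 * np.exp(d.get("ls", np.log(best_p.s / s0))),
                theta=th,
                flip=best_p.flip,
                sy=float(np.exp(d.get("lsy", np.log(best_p.sy)))),
            )

        start = {
            "ls": np.log(best_p.s / s0), "ty": best_p.ty, "tx": best_p.tx,
            "theta": best_p.theta, "lsy": np.log(best_p.sy),
        }
        x_start = np.array([start[d] for d in dims])
        simplex = [x_start]
        for i, d in enumerate(dims):
            x = x_start.copy()
            x[i] += span[d]
            simplex.append(x)
        optimize.minimize(
            lambda x: -consider(unpack(x)),
            x_start,
            method="Nelder-Mead",
            options={
                "initial_simplex": np.array(simplex),
                "maxiter": 120 * len(dims),
                "xatol": 0.05,
                "fatol": 0.005,
            },
        )

    assert best_j >= init_j
    placement = Placement(
        tx=best_p.tx / native_factor,
        ty=best_p.ty / native_factor,
        s=best_p.s / native_factor,
        theta=best_p.theta,
        flip=best_p.flip,
        sy=best_p.sy,
    )
    return JResult(
        model_id=model.model_id, placement=placement, J=best_j,
        S_area=best_inter, T_area=best_union,
    )


def render_fit(
    seed: BinarySilhouette, model: GeometricModel, result: JResult, n_boundary: int = 720
) -> np.ndarray:
    """Rasterize the fitted model on the seed's native (cropped) grid."""
    work = crop_mask(seed.mask, 2)
    rr, cc = np.nonzero(work)
    center = (float(rr.mean()), float(cc.mean()))
    verts = _place_polygon(model.polygon(n_boundary), center, result.placement)
    return fill_polygon(verts, work.shape)


def j_table(
    seeds_by_group: Mapping[str, Sequence[BinarySilhouette]],
    models: Sequence[GeometricModel],
    cfg: FitConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every model to every seed; per-seed and per-group J summaries.

    Returns ``(per_seed, summary)``. ``per_seed`` has one row per seed x
    model with the placement parameters; failed fits are recorded as missing
    (NaN J) without aborting the table. ``summary`` gives per group x model
    the mean, SD and CV of J, with the group's best (highest mean J) model
    flagged — the layout of the published comparison tables.
    """
    rows = []
    for group, seeds in seeds_by_group.items():
        if not len(seeds):
            raise ValueError(f"group {group!r} is empty")
        for i, seed in enumerate(seeds):
            label = seed.label or f"seed_{i:03d}"
            for model in models:
                try:
                    res = fit_model(seed, model, cfg)
                    rows.append(
                        {
                            "group": group, "seed_label": label,
                            "model_id": model.model_id, "J": res.J,
                            "s": res.placement.s, "tx": res.placement.tx,
                            "ty": res.placement.ty, "theta": res.placement.theta,
                            "flip": res.placement.flip,
                        }
                    )
                except ValueError as exc:
                    rows.append(
                        {
                            "group": group, "seed_label": label,
                            "model_id": model.model_id, "J": np.nan,
                            "s": np.nan, "tx": np.nan, "ty": np.nan,
                            "theta": np.nan, "flip": False, "error": str(exc),
                        }
                    )
    per_seed = pd.DataFrame(rows)

    summ = (
        per_seed.groupby(["group", "model_id"])["J"]
        .agg(mean_J="mean", sd_J=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    summ["cv_J"] = np.where(
        summ["mean_J"] > 0, summ["sd_J"] / summ["mean_J"] * 100.0, np.nan
    )
    best = summ.loc[summ.groupby("group")["mean_J"].idxmax(), ["group", "model_id"]]
    best_pairs = set(map(tuple, best.values))
    summ["best"] = [
        (g, m) in best_pairs for g, m in zip(summ["group"], summ["model_id"])
    ]
    return per_seed, summ
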