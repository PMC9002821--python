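"""Config-driven pipeline stages behind the command-line interface.

A single YAML configuration describes a run: calibration, the model set,
averaging threshold, registration options, significance level and (for
synthetic runs) the populations to simulate. Every stage writes fixed-schema
CSV/PNG outputs under one output root and appends to a run log, and a full
run is deterministic given the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .averaging import average_silhouette, build_occupancy
from .models import GeometricModel, load_model_image, make_model, model_presets
from .morphometry import (
    MORPHO_COLUMNS,
    SegmentationConfig,
    measure_population,
    orient_silhouette,
    segment_plate,
)
from .registration import FitConfig, fit_model, j_table
from .silhouette import BinarySilhouette
from .stats import compare_traits, format_table, table_markdown
from .synthetic import SyntheticSpec, generate_plate

__all__ = ["RunConfig", "run_all", "load_config"]

MORPHO_TRAITS = ["A_mm2", "P_mm", "L_mm", "W_mm", "AR", "C", "R"]


@dataclass
class RunConfig:
    """Validated run configuration (see README for the YAML schema)."""

    scale_mm_per_px: float = 0.005
    view: str = "lateral"
    models: list = field(default_factory=lambda: ["LM1", "LM4", "LM5"])
    tau: float = 0.8
    alpha: float = 0.05
    rng_seed: int = 0
    polarity: str = "dark"
    min_area_px: int = 100
    registration: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    plates: dict = field(default_factory=dict)  # population -> image path

    def fit_config(self) -> FitConfig:
        return FitConfig(**self.registration)

    def resolve_models(self) -> list[GeometricModel]:
        """Model ids become parametric presets; paths load raster models."""
        out = []
        for m in self.models:
            if isinstance(m, GeometricModel):
                out.append(m)
            elif m in model_presets():
                out.append(make_model(m))
            elif Path(str(m)).exists():
                out.append(load_model_image(m))
            else:
                raise FileNotFoundError(f"model {m!r}: not a preset and no such file")
        return out

    def digest(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = RunConfig(**data)
    for pop, plate in cfg.plates.items():
        if not Path(plate).exists():
            raise FileNotFoundError(f"plate for {pop!r} not found: {plate}")
    return cfg


def _log(out: Path, message: str) -> None:
    with open(out / "log.txt", "a") as fh:
        fh.write(message + "\n")


def stage_simulate(cfg: RunConfig, out: Path, seed: int | None = None) -> dict:
    """Generate plate images for each configured synthetic population."""
    out.mkdir(parents=True, exist_ok=True)
    (out / "plates").mkdir(exist_ok=True)
    base_seed = cfg.rng_seed if seed is None else seed
    plates = {}
    pops = cfg.simulate.get("populations", [])
    if not pops:
        raise ValueError("config has no simulate.populations")
    for i, pop in enumerate(pops):
        pop = dict(pop)
        name = pop.pop("name", f"pop{i}")
        spec = SyntheticSpec(rng_seed=base_seed + i, **pop)
        img, truth = generate_plate(spec)
        path = out / "plates" / f"{name}.png"
        Image.fromarray(img).save(path)
        truth.to_csv(out / "plates" / f"{name}_truth.csv", index=False)
        plates[name] = str(path)
        _log(out, f"simulate: {name} n={len(truth)} -> {path.name}")
    return plates


def stage_segment(
    cfg: RunConfig, plates: dict, out: Path
) -> dict[str, list[BinarySilhouette]]:
    """Segment and orient every plate; silhouettes written as binary PNG."""
    out.mkdir(parents=True, exist_ok=True)
    seg_cfg = SegmentationConfig(
        scale_mm_per_px=cfg.scale_mm_per_px,
        polarity=cfg.polarity,
        min_area_px=cfg.min_area_px,
        view=cfg.view,
    )
    populations = {}
    for name, plate in plates.items():
        sils, report = segment_plate(plate, seg_cfg)
        oriented = [orient_silhouette(s) for s in sils]
        pop_dir = out / "silhouettes" / name
        pop_dir.mkdir(parents=True, exist_ok=True)
        for s in oriented:
            s.to_png(pop_dir / f"{s.label}.png")
        populations[name] = oriented
        _log(
            out,
            f"segment: {name} kept={report.n_kept} "
            f"border_rejected={report.n_border_rejected} "
            f"small_rejected={report.n_small_rejected}",
        )
    return populations


def stage_measure(cfg: RunConfig, populations: dict, out: Path) -> pd.DataFrame:
    """Morphometry CSV plus the letters table across populations."""
    frames = []
    for name, seeds in populations.items():
        df = measure_population(seeds)
        df.insert(0, "group", name)
        frames.append(df)
    morpho = pd.concat(frames, ignore_index=True)
    morpho.to_csv(out / "morphometry.csv", index=False)
    if morpho["group"].nunique() > 1:
        comps = compare_traits(morpho, "group", MORPHO_TRAITS, alpha=cfg.alpha)
        table = format_table(morpho, comps, "group")
    else:
        table = format_table(morpho, {}, "group")
    table.to_csv(out / "morphometry_table.csv", index=False)
    (out / "morphometry_table.md").write_text(table_markdown(table))
    _log(out, f"measure: {len(morpho)} seeds in {morpho['group'].nunique()} groups")
    return morpho


def stage_average(cfg: RunConfig, populations: dict, out: Path) -> dict:
    """Average silhouette (and occupancy map PNG) per population."""
    avg_dir = out / "averages"
    avg_dir.mkdir(parents=True, exist_ok=True)
    averages = {}
    for name, seeds in populations.items():
        occ = build_occupancy(seeds)
        avg = average_silhouette(occ, tau=cfg.tau, label=f"{name}_avg", view=cfg.view)
        occ.to_png(avg_dir / f"{name}_{cfg.view}_occupancy.png")
        avg.to_png(avg_dir / f"{name}_{cfg.view}_avg.png")
        averages[name] = avg
        _log(out, f"average: {name} tau={cfg.tau} area_px={avg.area_px}")
    return averages


def stage_fit(
    cfg: RunConfig, populations: dict, averages: dict, out: Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """J index of averages and of every seed against the model set."""
    models = cfg.resolve_models()
    fit_cfg = cfg.fit_config()

    avg_rows = []
    for name, avg in averages.items():
        for model in models:
            res = fit_model(avg, model, fit_cfg)
            avg_rows.append({"group": name, "model_id": res.model_id, "J": res.J})
    j_avg = pd.DataFrame(avg_rows)
    best = j_avg.loc[j_avg.groupby("group")["J"].idxmax(), ["group", "model_id"]]
    pairs = set(map(tuple, best.values))
    j_avg["best"] = [(g, m) in pairs for g, m in zip(j_avg["group"], j_avg["model_id"])]
    j_avg.to_csv(out / "j_average.csv", index=False)

    per_seed, summary = j_table(populations, models, fit_cfg)
    per_seed.to_csv(out / "j_per_seed.csv", index=False)
    summary.to_csv(out / "j_summary.csv", index=False)
    _log(out, f"fit: {len(per_seed)} seed-model fits, {len(models)} models")
    return j_avg, per_seed, summary


def stage_stats(
    cfg: RunConfig, per_seed: pd.DataFrame, out: Path
) -> pd.DataFrame | None:
    """Letters table for per-seed J values by model column."""
    wide = per_seed.pivot_table(
        index=["group", "seed_label"], columns="model_id", values="J"
    ).reset_index()
    model_cols = [c for c in wide.columns if c not in ("group", "seed_label")]
    if wide["group"].nunique() > 1:
        comps = compare_traits(wide, "group", model_cols, alpha=cfg.alpha)
        table = format_table(wide, comps, "group")
    else:
        table = format_table(wide, {}, "group")
    table.to_csv(out / "j_index_table.csv", index=False)
    (out / "j_index_table.md").write_text(table_markdown(table))
    _log(out, f"stats: J comparison over {wide['group'].nunique()} groups")
    return table


def run_all(cfg: RunConfig, out: Path, seed: int | None = None) -> dict:
    """Full pipeline: (simulate ->) segment -> measure -> average -> fit -> stats.

    Produces the four table families: morphometry with letters, the
    average-silhouette J matrix, per-seed J with letters, and CV summaries
    (embedded in both letter tables). Returns a manifest of written files.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    _log(out, f"run: seedshape {__version__} config={cfg.digest()} seed={seed}")
    plates = dict(cfg.plates)
    if cfg.simulate:
        plates.update(stage_simulate(cfg, out, seed))
    if not plates:
        raise ValueError("nothing to do: no plates configured or simulated")
    populations = stage_segment(cfg, plates, out)
    stage_measure(cfg, populations, out)
    averages = stage_average(cfg, populations, out)
    _, per_seed, _ = stage_fit(cfg, populations, averages, out)
    stage_stats(cfg, per_seed, out)
    manifest = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"out": str(out), "files": manifest}
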