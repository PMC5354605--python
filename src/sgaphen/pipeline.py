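"""End-to-end orchestration: simulate -> quantify -> score -> phenotype -> stats.

A run is described by a :class:`RunConfig` (loadable from a YAML file with
one section per stage) and executed by :func:`run`, which resolves stage
dependencies, threads one root seed through every stochastic step, and
writes a manifest recording inputs, outputs, checksums and versions so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .colony_quant import fit_grid, quantify_colonies
from .interaction_scoring import hub_fraction, load_gene_list, recovery_metrics, score_screen
from .phenotype_quant import (
    elongation_score,
    measure_vacuoles,
    score_viability,
    segment_cells,
    summarize_elongation,
)
from .stats_report import unpaired_t, write_report
from .synthetic_data import (
    CellFieldConfig,
    ScreenConfig,
    generate_cell_field,
    generate_screen,
    render_plate_image,
)

log = logging.getLogger("sgaphen")

STAGES = ("screen", "quantify", "score", "cells", "phenotype", "stats")
_DEPS = {
    "quantify": ("screen",),
    "score": ("screen",),
    "phenotype": ("cells",),
    "stats": ("phenotype",),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    screen: dict = field(default_factory=dict)  # ScreenConfig overrides
    cells: dict = field(default_factory=dict)  # CellFieldConfig overrides
    scoring: dict = field(default_factory=dict)  # thresholds etc.
    hub_genes_path: str | None = None
    images_dir: str | None = None  # quantify real images instead of renders
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_stages(requested) -> list[str]:
    wanted: set[str] = set()

    def add(s: str) -> None:
        for d in _DEPS.get(s, ()):
            add(d)
        wanted.add(s)

    for s in requested:
        add(s)
    return [s for s in STAGES if s in wanted]


def run(config: RunConfig) -> dict:
    """Execute the selected stages and return the manifest dict.

    Stages run in dependency order; any referenced input path is validated
    before the first stage starts; a stage failure propagates (the CLI maps
    it to a non-zero exit).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.hub_genes_path is not None and not os.path.exists(config.hub_genes_path):
        raise FileNotFoundError(f"hub gene list not found: {config.hub_genes_path}")
    if config.images_dir is not None and not os.path.isdir(config.images_dir):
        raise FileNotFoundError(f"image directory not found: {config.images_dir}")

    os.makedirs(config.outdir, exist_ok=True)
    stages = _resolve_stages(config.stages)
    outputs: dict[str, str] = {}
    state: dict = {}

    for stage in stages:
        log.info("stage %s", stage)
        outputs.update(_STAGE_FUNCS[stage](config, state))

    manifest = {
        "package": "sgaphen",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": stages,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "outputs": {
            name: {"path": path, "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        },
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _stage_screen(config: RunConfig, state: dict) -> dict[str, str]:
    cfg = ScreenConfig(seed=config.seed, **config.screen)
    screen = generate_screen(cfg)
    state["screen"] = screen
    outdir = os.path.join(config.outdir, "screen")
    return screen.write(outdir)


def _stage_quantify(config: RunConfig, state: dict) -> dict[str, str]:
    """Render the first replicate/isolate plate pair and quantify it back.

    Exercises the image path of the pipeline on every run; with
    ``images_dir`` set, quantifies the user's TIFF/PNG plates instead.
    """
    outdir = os.path.join(config.outdir, "quantified")
    os.makedirs(outdir, exist_ok=True)
    out: dict[str, str] = {}
    screen = state["screen"]
    rows, cols = screen.config.rows, screen.config.cols
    if config.images_dir is not None:
        import imageio.v3 as iio

        frames = []
        for name in sorted(os.listdir(config.images_dir)):
            if not name.lower().endswith((".tif", ".tiff", ".png")):
                continue
            img = iio.imread(os.path.join(config.images_dir, name))
            grid = fit_grid(img, rows, cols)
            plate = quantify_colonies(img, grid, plate_id=os.path.splitext(name)[0])
            frames.append(plate.to_frame())
        path = os.path.join(outdir, "quantified_sizes.tsv")
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        out["quantified_sizes"] = path
        return out

    frames = []
    for plate in screen.select(replicate=1, isolate=1):
        # area_scale keeps the largest colony inside the rendering pitch
        pitch = 20
        scale = ((pitch / 2 - 4) ** 2 * np.pi) / max(plate.sizes.max(), 1.0)
        img, geometry, _ = render_plate_image(
            plate, pitch=pitch, area_scale=scale, seed=config.seed
        )
        tif = os.path.join(outdir, f"{plate.plate_id}.tiff")
        tifffile.imwrite(tif, img)
        out[f"image_{plate.plate_id}"] = tif
        fitted = fit_grid(img, rows, cols)
        q = quantify_colonies(
            img, fitted,
            plate_id=plate.plate_id, replicate=plate.replicate,
            isolate=plate.isolate, array_role=plate.array_role,
        )
        q.genes = plate.genes
        frames.append(q.to_frame())
    path = os.path.join(outdir, "quantified_sizes.tsv")
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    out["quantified_sizes"] = path
    return out


def _stage_score(config: RunConfig, state: dict) -> dict[str, str]:
    screen = state["screen"]
    robust, rep_tables = score_screen(screen.plates, **config.scoring)
    outdir = os.path.join(config.outdir, "interactions")
    os.makedirs(outdir, exist_ok=True)
    out = {}
    path = os.path.join(outdir, "robust_interactions.tsv")
    robust.to_csv(path, sep="\t", index=False)
    out["robust_interactions"] = path
    for i, tab in enumerate(rep_tables, start=1):
        p = os.path.join(outdir, f"replicate{i}_calls.tsv")
        tab.to_csv(p, sep="\t", index=False)
        out[f"replicate{i}_calls"] = p
    rec = recovery_metrics(robust, screen.truth)
    p = os.path.join(outdir, "recovery_metrics.tsv")
    rec.to_csv(p, sep="\t", index=False)
    out["recovery_metrics"] = p
    if config.hub_genes_path:
        hub = load_gene_list(config.hub_genes_path)
        negatives = robust.loc[robust["call"] == "negative", "gene"].tolist()
        if negatives:
            n_in, pct = hub_fraction(negatives, hub)
            p = os.path.join(outdir, "hub_fraction.tsv")
            pd.DataFrame(
                [{"n_negative": len(negatives), "n_in_hub": n_in, "percent": pct}]
            ).to_csv(p, sep="\t", index=False)
            out["hub_fraction"] = p
    state["robust"] = robust
    return out


def _stage_cells(config: RunConfig, state: dict) -> dict[str, str]:
    """Simulate round-cell and elongated-cell fields (two conditions)."""
    outdir = os.path.join(config.outdir, "cells")
    os.makedirs(outdir, exist_ok=True)
    out = {}
    fields = {}
    base = dict(config.cells)
    for i, (name, ratio) in enumerate([("round", 1.0), ("elongated", 2.5)]):
        overrides = dict(base)
        overrides.setdefault("axis_ratio_mean", ratio)
        if name == "round":
            overrides["axis_ratio_mean"] = ratio
        cfg = CellFieldConfig(seed=config.seed + i + 1, **overrides)
        fld = generate_cell_field(cfg)
        fields[name] = fld
        for chan in ("wall", "dead_stain", "vacuole"):
            p = os.path.join(outdir, f"{name}_{chan}.tiff")
            tifffile.imwrite(p, getattr(fld, chan))
            out[f"{name}_{chan}"] = p
        p = os.path.join(outdir, f"{name}_truth.tsv")
        fld.truth.to_csv(p, sep="\t", index=False)
        out[f"{name}_truth"] = p
    state["fields"] = fields
    return out


def _stage_phenotype(config: RunConfig, state: dict) -> dict[str, str]:
    outdir = os.path.join(config.outdir, "phenotypes")
    os.makedirs(outdir, exist_ok=True)
    out = {}
    rows = []
    per_cell = []
    elong = {}
    for name, fld in state["fields"].items():
        masks = segment_cells(fld.wall)
        scores = [elongation_score(m) for m in masks]
        elong[name] = scores
        for m, s in zip(masks, scores):
            per_cell.append(
                {"condition": name, "cell": m.label, "area_px2": m.area,
                 "perimeter_px": m.perimeter, "elongation": s}
            )
        n_per = min(30, max(1, len(scores)))
        summ = summarize_elongation(scores, n_per_dataset=n_per)
        viab = score_viability(fld.wall, fld.dead_stain, n_scored=500)
        try:
            vacs = measure_vacuoles(fld.vacuole, fld.config.pixel_size)
            vac_mean = float(np.mean([v.diameter_um for v in vacs]))
            n_vac = len(vacs)
        except ValueError:
            vac_mean, n_vac = float("nan"), 0
        rows.append(
            {
                "condition": name,
                "elongation_mean": summ["mean"],
                "elongation_sem": summ["sem"],
                "n_cells": len(scores),
                "viability_percent": viab.viability_percent,
                "n_scored": viab.n_total,
                "vacuole_diameter_um": vac_mean,
                "n_vacuoles": n_vac,
            }
        )
    p = os.path.join(outdir, "per_cell_shapes.tsv")
    pd.DataFrame(per_cell).to_csv(p, sep="\t", index=False)
    out["per_cell_shapes"] = p
    p = os.path.join(outdir, "phenotype_summary.tsv")
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    out["phenotype_summary"] = p
    state["elongation"] = elong
    return out


def _stage_stats(config: RunConfig, state: dict) -> dict[str, str]:
    outdir = os.path.join(config.outdir, "stats")
    os.makedirs(outdir, exist_ok=True)
    elong = state["elongation"]
    results = []
    names = list(elong)
    if len(names) >= 2:
        a, b = elong[names[0]], elong[names[1]]
        res = unpaired_t(a, b)
        res.groups[0].label, res.groups[1].label = names[0], names[1]
        results.append(res)
    tsv = os.path.join(outdir, "tests.tsv")
    txt = os.path.join(outdir, "tests.txt")
    write_report(results, tsv, txt)
    return {"stats_tests": tsv, "stats_report": txt}


_STAGE_FUNCS = {
    "screen": _stage_screen,
    "quantify": _stage_quantify,
    "score": _stage_score,
    "cells": _stage_cells,
    "phenotype": _stage_phenotype,
    "stats": _stage_stats,
}
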