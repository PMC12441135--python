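"""Configuration, orchestration and tidy outputs for the full workflow.

A TOML config declares the inputs (cell-table CSV, trace CSV, mask TIFFs —
or a ``[simulate]`` section generating them) and per-stage settings; one
root seed governs every stochastic stage through derived substreams, so a
rerun with the same config and seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import __version__
from . import clones as clones_mod
from . import core_model, ephys, morphometry, ringstats, synthetic

log = logging.getLogger("clonemap")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage and offending entity."""


@dataclass
class PipelineConfig:
    seed: int
    raw: dict[str, Any] = field(default_factory=dict)
    base_dir: Path = Path(".")

    @classmethod
    def from_toml(cls, path: str | Path, seed: Optional[int] = None) -> "PipelineConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if seed is None:
            if "seed" not in raw:
                raise PipelineError("config: a seed is mandatory")
            seed = int(raw["seed"])
        return cls(seed=seed, raw=raw, base_dir=path.parent)

    def section(self, name: str) -> dict[str, Any]:
        return dict(self.raw.get(name, {}))

    def digest(self) -> str:
        payload = json.dumps({"seed": self.seed, "config": self.raw},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _grid_from_config(cfg: dict[str, Any]) -> ringstats.RingGrid:
    if "radii" in cfg:
        start, stop, step = cfg["radii"]
        radii = tuple(float(r) for r in np.arange(start, stop + step / 2, step))
    else:
        radii = ringstats.RingGrid().radii
    return ringstats.RingGrid(radii=radii, width=float(cfg.get("width", 20.0)))


def _simulate_cells(sim: dict[str, Any], seed: int) -> core_model.StudyTable:
    kind = sim.get("kind", "random")
    bounds = tuple(float(b) for b in sim.get("bounds", (580.0, 580.0, 30.0)))
    n_mice = int(sim.get("n_mice", 3))
    spm = int(sim.get("stacks_per_mouse", 3))
    condition = sim.get("condition", "stroke" if kind == "clonal" else "contralateral")
    timepoint = sim.get("timepoint", "2w")
    color_freqs = tuple(float(p) for p in sim.get("color_freqs",
                                                  (0.25, 0.25, 0.25, 0.25)))
    if kind == "random":
        intensity = float(sim.get("intensity", 1653.0))

        def make(mouse_id: str, image_id: str, rng: np.random.Generator
                 ) -> core_model.ImageStack:
            return synthetic.simulate_random_pattern(
                intensity, bounds, color_freqs, rng, image_id=image_id,
                mouse_id=mouse_id, condition=condition, timepoint=timepoint)
    elif kind == "clonal":
        cfg = synthetic.ClonalSimConfig(
            parent_intensity=float(sim.get("parent_intensity", 300.0)),
            offspring_mean=float(sim.get("offspring_mean", 5.0)),
            dispersion_sigma=float(sim.get("dispersion_sigma", 15.0)),
            background_intensity=float(sim.get("background_intensity", 400.0)),
            color_freqs=color_freqs, bounds=bounds)

        def make(mouse_id: str, image_id: str, rng: np.random.Generator
                 ) -> core_model.ImageStack:
            stack, _ = synthetic.simulate_clonal_pattern(
                cfg, image_id=image_id, mouse_id=mouse_id,
                condition=condition, timepoint=timepoint, seed=rng)
            return stack
    else:
        raise PipelineError(f"simulate: unknown kind {kind!r}")
    return synthetic.simulate_study(n_mice, spm, make, seed=seed)


def _load_cells(config: PipelineConfig) -> core_model.StudyTable:
    inputs = config.section("inputs")
    if "cells" in inputs:
        path = config.base_dir / inputs["cells"]
        if not path.exists():
            raise PipelineError(
                f"core_model.read_cell_table: missing cells file {path}")
        try:
            return core_model.read_cell_table(path)
        except Exception as exc:
            raise PipelineError(f"core_model.read_cell_table: {exc}") from exc
    sim = config.section("simulate")
    if sim:
        return _simulate_cells(sim, seed=config.seed)
    raise PipelineError("inputs: no cells file and no [simulate] section")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every configured stage and write tidy CSVs plus a run manifest.

    Deterministic: the output directory contents are a pure function of
    (inputs, config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config_digest": config.digest(),
                                "seed": config.seed,
                                "clonemap_version": __version__,
                                "stages": []}

    study: Optional[core_model.StudyTable] = None
    needs_cells = ("ringstats" in config.raw or "clones" in config.raw
                   or "simulate" in config.raw
                   or "cells" in config.section("inputs"))
    if needs_cells:
        study = _load_cells(config)
        violations = core_model.validate_study(study)
        if violations:
            raise PipelineError(f"core_model.validate_study: {violations[0]}")
        core_model.write_cell_table(study, out / "cells.csv")
        log.info("cells: %d stacks, %d cells", len(study.stacks), study.n_cells())
        manifest["stages"].append("cells")

    if study is not None and "ringstats" in config.raw:
        cfg = config.section("ringstats")
        grid = _grid_from_config(cfg)
        sub = out / "ringstats"
        sub.mkdir(exist_ok=True)
        groups = sorted({(s.timepoint, s.condition) for s in study.stacks})
        for tp, cond in groups:
            group = study.subset(timepoint=tp, condition=cond)
            try:
                analysis = ringstats.analyze_group(
                    group, grid,
                    n_sims=int(cfg.get("n_sims", 1000)),
                    percentiles=tuple(cfg.get("percentiles", (2.0, 98.0))),
                    seed=config.seed, metric=cfg.get("metric", "xy"),
                    edge_correction=bool(cfg.get("edge_correction", True)))
            except Exception as exc:
                raise PipelineError(f"ringstats.analyze_group[{tp},{cond}]: {exc}") from exc
            analysis.to_frame().to_csv(sub / f"band_{tp}_{cond}.csv",
                                       index=False, float_format="%.10g")
            log.info("ringstats %s/%s: %d/%d radii above the band",
                     tp, cond, int(analysis.flags.sum()), len(grid.radii))
        manifest["stages"].append("ringstats")

    if study is not None and "clones" in config.raw:
        cfg = config.section("clones")
        params = clones_mod.CloneParams(
            epsilon=float(cfg.get("epsilon", 50.0)),
            min_cells=int(cfg.get("min_cells", 2)),
            metric=cfg.get("metric", "3d"))
        sub = out / "clones"
        sub.mkdir(exist_ok=True)
        tables = []
        for s in study.stacks:
            cs = clones_mod.detect_clones(s, params)
            tables.append(clones_mod.clone_table(s, cs))
        pd.concat(tables, ignore_index=True).to_csv(
            sub / "clone_table.csv", index=False, float_format="%.10g")
        clones_mod.group_summary(study, params).to_csv(
            sub / "group_summary.csv", index=False, float_format="%.10g")
        log.info("clones: %d stacks analysed", len(study.stacks))
        manifest["stages"].append("clones")

    if "ephys" in config.raw:
        cfg = config.section("ephys")
        traces_path = config.base_dir / config.section("inputs").get("traces", "traces.csv")
        if not traces_path.exists():
            raise PipelineError(f"ephys.read_traces: missing traces file {traces_path}")
        recordings = ephys.read_traces(traces_path)
        sub = out / "ephys"
        sub.mkdir(exist_ok=True)
        rows = []
        by_cell: dict[str, dict[float, ephys.IVRecording]] = {}
        for holding, recs in recordings.items():
            for rec in recs:
                by_cell.setdefault(rec.cell_id, {})[holding] = rec
        for cell_id, recs in sorted(by_cell.items()):
            if -70.0 not in recs or -20.0 not in recs:
                raise PipelineError(
                    f"ephys.extract_membrane_properties: cell {cell_id} lacks "
                    "a −70/−20 mV holding pair")
            props = ephys.extract_membrane_properties(
                recs[-70.0], recs[-20.0],
                theta_out=float(cfg.get("theta_out", 0.1)),
                theta_in=float(cfg.get("theta_in", 0.1)),
                strong_threshold=float(cfg.get("strong_threshold", 0.5)))
            rows.append({"cell_id": cell_id, "R_m_MOhm": props.R_m,
                         "C_m_pF": props.C_m, "V_rev_mV": props.V_rev,
                         "G_out_nS_per_pF": props.G_out_spec,
                         "G_in_nS_per_pF": props.G_in_spec,
                         "current_class": props.current_class})
        pd.DataFrame(rows).to_csv(sub / "membrane_properties.csv",
                                  index=False, float_format="%.10g")
        log.info("ephys: %d cells", len(rows))
        manifest["stages"].append("ephys")

    if "morph" in config.raw:
        cfg = config.section("morph")
        masks = config.section("inputs").get("masks", [])
        voxel_size = tuple(float(v) for v in cfg.get("voxel_size", (1.0, 1.0, 1.0)))
        sub = out / "morph"
        sub.mkdir(exist_ok=True)
        rows = []
        for mask_path in masks:
            p = config.base_dir / mask_path
            if not p.exists():
                raise PipelineError(f"morphometry: missing mask {p}")
            mask = core_model.read_mask(p, voxel_size)
            f = morphometry.extract_features(mask)
            rows.append({"mask": str(mask_path), "volume_um3": f.volume,
                         "surface_area_um2": f.surface_area,
                         "sa_to_vol_per_um": f.sa_to_vol,
                         "sphericity": f.sphericity,
                         "ellipsoid_r1_um": f.ellipsoid_radii[0],
                         "ellipsoid_r2_um": f.ellipsoid_radii[1],
                         "ellipsoid_r3_um": f.ellipsoid_radii[2],
                         "longest_shortest_path_um": f.longest_shortest_path,
                         "total_skeleton_length_um": f.total_skeleton_length,
                         "touches_boundary": f.touches_boundary})
        pd.DataFrame(rows).to_csv(sub / "features.csv", index=False,
                                  float_format="%.10g")
        log.info("morph: %d masks", len(rows))
        manifest["stages"].append("morph")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def group_compare(table: pd.DataFrame, value: str, group: str) -> pd.DataFrame:
    """Descriptive per-group statistics (mean ± s.e.m., median ± IQR) plus a
    standard nonparametric test p-value (Mann-Whitney U for two groups,
    Kruskal-Wallis otherwise).  Descriptive reporting plumbing only."""
    groups = [(g, sub[value].dropna().to_numpy())
              for g, sub in table.groupby(group, sort=True)]
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = [a for _, a in groups]
    if len(groups) == 2:
        if np.array_equal(arrays[0], arrays[1]):
            pval = 1.0
        else:
            pval = float(sstats.mannwhitneyu(*arrays).pvalue)
        test = "mann-whitney"
    else:
        pval = float(sstats.kruskal(*arrays).pvalue)
        test = "kruskal-wallis"
    rows = []
    for g, a in groups:
        q1, med, q3 = np.percentile(a, [25, 50, 75]) if a.size else (np.nan,) * 3
        rows.append({group: g, "n": a.size,
                     "mean": float(a.mean()) if a.size else np.nan,
                     "sem": float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else np.nan,
                     "median": float(med), "iqr_low": float(q1),
                     "iqr_high": float(q3), "test": test, "p_value": pval})
    return pd.DataFrame(rows)
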