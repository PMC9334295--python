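"""End-to-end orchestration: simulate -> segment -> graph -> topology ->
morphology -> dose-group statistics.

A run is driven by a flat key=value config file (see ``configs/default.cfg``
for a commented template) plus a master seed.  All intermediate tables are
written as CSV with fixed schemas; a plain-text run log records every
parameter and seed so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets as presets_mod
from .graph import WaxmanParams, build_graph
from .segmentation import SegmentationParams, load_tiff, segment_image
from .stats import DoseGroup, compare_doses
from .synthetic import emulate_dose_series
from .topology import small_worldness

__all__ = ["PipelineStageError", "parse_config", "run_pipeline", "discover_images"]

_DOSE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*Gy", re.IGNORECASE)

_DEFAULT_CONFIG = {
    "preset": "minimal",
    "input_dir": "",
    "line": "SYN",
    "images_per_dose": "3",
    "seed": "1",
    "filter_window_px": "3",
    "min_component_px": "8",
    "connectivity": "8",
    "hmin_depth": "2.0",
    "clear_border": "true",
    "alpha": "1.0",
    "beta": "0.025",
    "R": "0.05",
    "L": "per_image",
    "er_replicates": "20",
    "alpha_level": "0.05",
    "welch": "false",
    "test_metrics": "sw,area",
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending file."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def parse_config(path: str | Path | None) -> dict[str, str]:
    """Read a flat ``key = value`` config file ('#' comments); unknown keys
    are rejected, missing ones take defaults."""
    cfg = dict(_DEFAULT_CONFIG)
    if path is None:
        return cfg
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _DEFAULT_CONFIG:
            raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
        cfg[key] = val
    return cfg


def _bool(s: str) -> bool:
    return s.strip().lower() in ("1", "true", "yes", "on")


def discover_images(root: str | Path) -> pd.DataFrame:
    """Find TIFFs under ``root`` and infer (line, dose, image name).

    Accepts both the flat generator layout ``<line>_<dose>Gy_<rep>.tif`` and a
    nested ``<line>/<dose>Gy/*.tif`` layout; the dose is parsed from the
    filename or an enclosing directory name.
    """
    root = Path(root)
    rows = []
    for p in sorted(root.rglob("*.tif")) + sorted(root.rglob("*.tiff")):
        m = _DOSE_RE.search(p.stem)
        if m:
            dose = float(m.group(1))
            line = p.stem.split("_")[0]
        else:
            m = next((_DOSE_RE.search(q.name) for q in p.parents if _DOSE_RE.search(q.name)), None)
            if m is None:
                continue
            dose = float(m.group(1))
            line = p.parent.parent.name if p.parent.parent != root.parent else "unknown"
        rows.append({"path": str(p), "image": p.name, "line": line, "dose": dose})
    if not rows:
        raise PipelineStageError("discover", f"no TIFF images with a parsable dose under {root}")
    return pd.DataFrame(rows)


def _seg_params(cfg: dict[str, str]) -> SegmentationParams:
    return SegmentationParams(
        filter_window_px=int(cfg["filter_window_px"]),
        min_component_px=int(cfg["min_component_px"]),
        connectivity=int(cfg["connectivity"]),
        hmin_depth=float(cfg["hmin_depth"]),
        clear_border=_bool(cfg["clear_border"]),
    )


def _waxman_params(cfg: dict[str, str]) -> WaxmanParams:
    L = None if cfg["L"].strip().lower() in ("", "per_image", "auto") else float(cfg["L"])
    return WaxmanParams(alpha=float(cfg["alpha"]), beta=float(cfg["beta"]),
                        R=float(cfg["R"]), L=L)


def _preset_configs(name: str):
    if name == "minimal":
        return presets_mod.minimal_preset()
    if name == "dose_series":
        return presets_mod.dose_series_presets()
    if name == "matched_pair":
        return presets_mod.matched_pair()
    raise ValueError(f"unknown preset {name!r} (use minimal|dose_series|matched_pair|none)")


def run_pipeline(
    config_file: str | Path | None,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute the full pipeline and write the report bundle to ``out_dir``.

    Outputs: ``images/`` (synthetic TIFFs + ground truth, when simulating),
    ``cells.csv``, ``edges.csv``, ``metrics.csv``, ``summary.csv``,
    ``pvalues.csv`` and ``run_log.txt``.  Returns the tables in a dict.
    """
    cfg = parse_config(config_file)
    if seed is not None:
        cfg["seed"] = str(int(seed))
    master_seed = int(cfg["seed"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg["preset"].strip().lower() != "none":
        try:
            emulate_dose_series(
                _preset_configs(cfg["preset"].strip().lower()),
                images_per_dose=int(cfg["images_per_dose"]),
                seed=master_seed,
                out_dir=out_dir / "images",
                line=cfg["line"],
            )
        except Exception as e:
            raise PipelineStageError("simulate", str(e)) from e
        image_root = out_dir / "images"
    else:
        if not cfg["input_dir"]:
            raise PipelineStageError("simulate", "preset=none requires input_dir")
        image_root = Path(cfg["input_dir"])

    manifest = discover_images(image_root)
    seg_params = _seg_params(cfg)
    wax = _waxman_params(cfg)
    er_reps = int(cfg["er_replicates"])

    cell_rows, edge_rows, metric_rows = [], [], []
    groups: dict[tuple[str, float], DoseGroup] = {}
    for img_idx, rec in enumerate(manifest.itertuples()):
        try:
            image = load_tiff(rec.path)
            _, cells = segment_image(image, seg_params)
        except Exception as e:
            raise PipelineStageError("segment", f"{rec.image}: {e}") from e
        if len(cells) < 2:
            raise PipelineStageError("segment", f"{rec.image}: fewer than 2 nuclei found")
        for c in cells:
            cell_rows.append(
                {"image": rec.image, "cell_id": c.cell_id, "x": c.x, "y": c.y,
                 "area_px": c.area, "perimeter_px": c.perimeter,
                 "eccentricity": c.eccentricity, "roundness": c.roundness}
            )
        coords = np.array([[c.x, c.y] for c in cells])
        try:
            g = build_graph(coords, wax)
        except Exception as e:
            raise PipelineStageError("graph", f"{rec.image}: {e}") from e
        ii, jj = np.nonzero(np.triu(g.adjacency, k=1))
        dists = np.hypot(*(coords[ii] - coords[jj]).T)
        for a, b, d in zip(ii, jj, dists):
            edge_rows.append({"image": rec.image, "node_i": int(a), "node_j": int(b),
                              "distance_px": round(float(d), 4)})
        try:
            img_seed = int(
                np.random.SeedSequence(entropy=master_seed, spawn_key=(1, img_idx))
                .generate_state(1)[0] % (2**31)
            )
            tm = small_worldness(g, replicates=er_reps, seed=img_seed)
        except Exception as e:
            raise PipelineStageError("topology", f"{rec.image}: {e}") from e
        from .graph import max_pairwise_distance

        L_used = wax.L if wax.L is not None else max_pairwise_distance(coords)
        metric_rows.append(
            {"image": rec.image, "dose": rec.dose, **asdict(tm),
             "R": wax.R, "alpha": wax.alpha, "beta": wax.beta, "L": round(L_used, 4)}
        )
        key = (rec.line, rec.dose)
        grp = groups.setdefault(key, DoseGroup(cell_line_label=rec.line, dose=rec.dose))
        grp.per_image_metrics.append(tm)
        grp.per_image_morphology.append(cells)

    cells_df = pd.DataFrame(cell_rows)
    edges_df = pd.DataFrame(edge_rows)
    metrics_df = pd.DataFrame(metric_rows)

    # Fig-4-style summary: per-dose mean +/- sd of each reported metric
    summary_rows = []
    for (line, dose), grp in sorted(groups.items()):
        for metric in ("k_mean", "cc", "cpl", "sw", "area", "perimeter",
                       "eccentricity", "roundness"):
            vals = grp.metric_values(metric)
            summary_rows.append(
                {"line": line, "dose": dose, "metric": metric,
                 "mean": float(np.mean(vals)),
                 "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                 "n_images": len(vals)}
            )
    summary_df = pd.DataFrame(summary_rows)

    # Fig-6-style raw p-values vs the 0 Gy group (no multiplicity correction)
    pvalue_frames = []
    by_line: dict[str, list[DoseGroup]] = {}
    for (line, _), grp in groups.items():
        by_line.setdefault(line, []).append(grp)
    for line, grps in sorted(by_line.items()):
        if len(grps) < 2 or not any(g.dose == 0 for g in grps):
            continue
        for metric in [m.strip() for m in cfg["test_metrics"].split(",") if m.strip()]:
            try:
                tab = compare_doses(grps, metric=metric,
                                    alpha=float(cfg["alpha_level"]), welch=_bool(cfg["welch"]))
            except Exception as e:
                raise PipelineStageError("analyze", f"line {line}, metric {metric}: {e}") from e
            tab.insert(0, "line", line)
            pvalue_frames.append(tab)
    pvalues_df = pd.concat(pvalue_frames, ignore_index=True) if pvalue_frames else pd.DataFrame()

    cells_df.to_csv(out_dir / "cells.csv", index=False)
    edges_df.to_csv(out_dir / "edges.csv", index=False)
    metrics_df.to_csv(out_dir / "metrics.csv", index=False)
    summary_df.to_csv(out_dir / "summary.csv", index=False)
    pvalues_df.to_csv(out_dir / "pvalues.csv", index=False)

    log = ["colonynet pipeline run", "----------------------"]
    log += [f"{k} = {v}" for k, v in sorted(cfg.items())]
    log += [f"n_images = {len(manifest)}",
            "note: p-values are raw (no multiple-testing correction), "
            "matching the per-dose presentation they mirror"]
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")

    return {"config": cfg, "cells": cells_df, "edges": edges_df, "metrics": metrics_df,
            "summary": summary_df, "pvalues": pvalues_df, "groups": groups,
            "out_dir": out_dir}
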