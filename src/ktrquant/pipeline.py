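"""End-to-end run orchestration: simulate -> segment -> quantify -> qc -> stats.

A run is driven by one YAML config with per-module blocks and a global
seed; identical config + seed reproduce identical CSV outputs. Each run
writes a machine-readable ``manifest.json`` recording the config hash,
seed, library versions and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import FieldImage, LabelMap
from .expression import delta_delta_ct, results_to_frame
from .io import (dump_yaml, frame_to_csv, load_yaml, write_field_tiff,
                 write_labelmap_tiff)
from .qc import QcParams, flag_geometry, flag_outliers, qc_report
from .quantify import MorphologyParams, measure_field, records_to_frame
from .segmentation import SegmentationParams, segment_cells, segment_nuclei
from .stats import (activity_length_table, compare_conditions,
                    comparisons_to_frame, summaries_to_frame, summarize,
                    MEASUREMENTS)
from .synthetic import SceneSpec, generate_field, scene_for_condition

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "RunConfig", "run_pipeline", "simulate_experiment",
           "process_fields", "field_seed"]


class ConfigError(ValueError):
    """Invalid run configuration (reported before any computation)."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int
    conditions: list[dict]          # [{name, preset, n_fields, overrides}]
    scene: dict                     # SceneSpec overrides shared by all arms
    segmentation: SegmentationParams
    morphology: MorphologyParams
    qc: QcParams
    comparisons: list[tuple[str, str]]
    expression: dict
    write_images: bool
    make_figures: bool
    raw: dict

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        if not isinstance(cfg, dict):
            raise ConfigError("config must be a mapping")
        conditions = cfg.get("conditions")
        if not conditions:
            raise ConfigError("config must list at least one condition")
        names = [c.get("name") for c in conditions]
        if None in names or len(set(names)) != len(names):
            raise ConfigError("every condition needs a unique 'name'")
        for c in conditions:
            if int(c.get("n_fields", 0)) < 1:
                raise ConfigError(f"condition {c['name']!r}: n_fields must be >= 1")
        comparisons = [tuple(pair) for pair in
                       cfg.get("stats", {}).get("comparisons", [])]
        for pair in comparisons:
            if len(pair) != 2 or any(p not in names for p in pair):
                raise ConfigError(
                    f"comparison {pair} references unknown condition "
                    f"(known: {names})")
        try:
            seg = SegmentationParams(**cfg.get("segmentation", {}))
            morph = MorphologyParams(**cfg.get("morphology", {}))
            qc = QcParams(**_listify(cfg.get("qc", {})))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid parameter block: {exc}") from exc
        out_cfg = cfg.get("output", {})
        return cls(
            seed=int(cfg.get("seed", 0)),
            conditions=[{
                "name": c["name"],
                "preset": c.get("preset"),
                "n_fields": int(c["n_fields"]),
                "overrides": c.get("overrides", {}) or {},
            } for c in conditions],
            scene=_tuplify(cfg.get("scene", {}) or {}),
            segmentation=seg, morphology=morph, qc=qc,
            comparisons=comparisons,
            expression=cfg.get("expression", {}) or {},
            write_images=bool(out_cfg.get("write_images", False)),
            make_figures=bool(out_cfg.get("make_figures", False)),
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(load_yaml(path))


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _listify(d: dict) -> dict:
    # yaml gives lists where dataclasses want tuples; QcParams accepts both
    return _tuplify(d)


def field_seed(run_seed: int, index: int) -> int:
    """Deterministic per-field seed derived from the run seed (< 2**31)."""
    return (run_seed * 100_003 + 7919 * index + 1) % (2 ** 31)


def simulate_experiment(
    config: RunConfig,
) -> tuple[list[FieldImage], list[pd.DataFrame], list[tuple[LabelMap, LabelMap]]]:
    """Generate all fields of all condition arms with ground truth."""
    fields, truths, truth_maps = [], [], []
    idx = 0
    for cond in config.conditions:
        base = SceneSpec(**config.scene) if config.scene else SceneSpec()
        for j in range(cond["n_fields"]):
            overrides = dict(_tuplify(cond["overrides"]),
                             rng_seed=field_seed(config.seed, idx))
            if cond["preset"]:
                spec = scene_for_condition(base, cond["preset"], **overrides)
            else:
                spec = base.replace(**overrides)
            fid = f"{cond['name']}_f{j}"
            field, gt, nuc, cell = generate_field(spec, field_id=fid,
                                                  condition=cond["name"])
            gt.insert(0, "field_id", fid)
            gt.insert(1, "condition", cond["name"])
            fields.append(field)
            truths.append(gt)
            truth_maps.append((nuc, cell))
            idx += 1
    return fields, truths, truth_maps


def process_fields(
    fields: list[FieldImage],
    seg_params: SegmentationParams,
    morph_params: MorphologyParams,
) -> tuple[pd.DataFrame, list[tuple[LabelMap, LabelMap]]]:
    """Segment and measure a list of fields -> per-cell record table."""
    all_records = []
    maps = []
    for field in fields:
        nuclei = segment_nuclei(field.dna, seg_params)
        cells = segment_cells(field.reporter, nuclei, seg_params)
        records = measure_field(field, nuclei, cells, seg_params, morph_params)
        logger.info("field %s: %d nuclei, %d cells measured",
                    field.field_id, nuclei.ids.size, len(records))
        all_records.extend(records)
        maps.append((nuclei, cells))
    return records_to_frame(all_records), maps


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Stage order: simulate -> segment -> quantify -> qc -> stats; the qPCR
    stage runs independently when the config's ``expression`` block names
    an input CSV. Partial outputs are retained if a stage fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": _versions(),
        "stages": {},
    }
    dump_yaml(out / "config_used.yaml", config.raw)

    stage = "simulate"
    try:
        fields, truths, _ = simulate_experiment(config)
        gt = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
        frame_to_csv(gt, out / "ground_truth.csv")
        manifest["stages"][stage] = {"n_fields": len(fields),
                                     "n_cells_true": int(len(gt))}
        if config.write_images:
            img_dir = out / "fields"
            img_dir.mkdir(exist_ok=True)
            for f in fields:
                write_field_tiff(img_dir / f"{f.field_id}.tif", f)

        stage = "segment+quantify"
        cells_df, maps = process_fields(fields, config.segmentation,
                                        config.morphology)
        frame_to_csv(cells_df, out / "cells.csv")
        manifest["stages"][stage] = {"n_cells_measured": int(len(cells_df))}
        if config.write_images:
            lab_dir = out / "labels"
            lab_dir.mkdir(exist_ok=True)
            for f, (nuc, cell) in zip(fields, maps):
                write_labelmap_tiff(lab_dir / f"{f.field_id}_nuclei.tif", nuc)
                write_labelmap_tiff(lab_dir / f"{f.field_id}_cells.tif", cell)

        stage = "qc"
        qced = flag_outliers(flag_geometry(cells_df, config.qc), config.qc)
        frame_to_csv(qced, out / "cells_qc.csv")
        report = qc_report(qced)
        frame_to_csv(report, out / "qc_report.csv")
        manifest["stages"][stage] = {
            "n_pass": int(qced["qc_pass"].sum()),
            "n_fail": int((~qced["qc_pass"]).sum()),
        }

        stage = "stats"
        passing = qced[qced["qc_pass"]]
        summaries = summarize(passing)
        frame_to_csv(summaries_to_frame(summaries), out / "summaries.csv")
        results = [compare_conditions(passing, a, b, m)
                   for (a, b) in config.comparisons for m in MEASUREMENTS]
        frame_to_csv(comparisons_to_frame(results), out / "comparisons.csv")
        joint, corr = activity_length_table(passing)
        frame_to_csv(joint, out / "activity_length.csv")
        frame_to_csv(corr, out / "activity_length_correlations.csv")
        manifest["stages"][stage] = {"n_summaries": len(summaries),
                                     "n_comparisons": len(results)}
        if config.make_figures:
            _violin_figure(passing, summaries, out / "violins.png")

        stage = "expression"
        qpcr_csv = config.expression.get("input_csv")
        if qpcr_csv:
            qdf = pd.read_csv(qpcr_csv)
            res = delta_delta_ct(
                qdf,
                reference_gene=config.expression.get("reference_gene", "GAPDH"),
                control_condition=config.expression.get(
                    "control_condition", "DMSO"),
                equal_var=bool(config.expression.get("equal_var", False)),
                log_base=int(config.expression.get("log_base", 2)),
            )
            frame_to_csv(results_to_frame(res), out / "expression.csv")
            manifest["stages"][stage] = {"n_results": len(res)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import scipy
    import skimage

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
    }


def _violin_figure(passing: pd.DataFrame, summaries, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, col, fm_attr, title in (
        (axes[0], "erk_activity", "field_medians_activity", "ERK activity (C/N)"),
        (axes[1], "process_length_px", "field_medians_length",
         "process length (px)"),
    ):
        conditions = [s.condition for s in summaries]
        data = [passing.loc[passing["condition"] == c, col].dropna()
                for c in conditions]
        ax.violinplot(data, showmedians=True)
        for i, s in enumerate(summaries, start=1):
            fm = getattr(s, fm_attr)
            ax.plot(np.full(len(fm), i), fm, "k.", ms=6)
        ax.set_xticks(range(1, len(conditions) + 1), conditions)
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
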