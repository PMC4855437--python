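"""End-to-end pipeline: read -> standardize -> fingerprint -> PCA ->
grid -> color -> export, with diagnostics."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem_io, fingerprints, projection, scene, space3d

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration before any compute."""


@dataclass
class PipelineConfig:
    input_path: str
    out_dir: str
    fingerprint_kind: str = "mqn"
    descriptor: str = "ring_count"
    n_bins: int = space3d.DEFAULT_N_BINS
    max_hac: int = chem_io.DEFAULT_MAX_HAC
    seed: int = 0
    n_pairs: int = 1_000_000
    max_coverage_k: int = 10
    overlay_path: str | None = None
    input_format: str = "auto"  # auto | smiles | sdf


@dataclass
class PipelineResult:
    mols: list
    rejections: chem_io.RejectionLog
    fps: np.ndarray
    model: projection.PCAModel
    coords: np.ndarray
    grid: space3d.Grid3D
    scene: scene.Scene
    diagnostics: dict
    artifacts: dict[str, str] = field(default_factory=dict)


def _validate(config: PipelineConfig) -> None:
    if config.fingerprint_kind not in fingerprints.KIND_LENGTHS:
        raise ConfigError(f"unknown fingerprint kind {config.fingerprint_kind!r}")
    if config.descriptor not in space3d.PROPERTY_COLUMNS:
        raise ConfigError(f"unknown descriptor {config.descriptor!r}")
    if config.n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    if not os.path.exists(config.input_path):
        raise ConfigError(f"input file not found: {config.input_path}")


def read_library(path: str, fmt: str = "auto", log=None):
    if fmt == "auto":
        fmt = "sdf" if str(path).lower().endswith(".sdf") else "smiles"
    if fmt == "sdf":
        return chem_io.read_sdf(path, log=log)
    return chem_io.read_smiles_file(path, log=log)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all artifacts into ``out_dir``.

    Artifacts: standardized.smi, rejections.tsv, fingerprints.csv,
    model.json, coords.csv, grid.json, scene.json, diagnostics.json,
    scene.html, run.log.
    """
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("stage=read input=%s", config.input_path)
        rejections = chem_io.RejectionLog()
        records = read_library(config.input_path, config.input_format, log=rejections)

        logger.info("stage=standardize n_records=%d", len(records))
        mols, rejections = chem_io.standardize_library(
            records, max_hac=config.max_hac, log=rejections
        )
        logger.info("stage=standardize kept=%d rejected=%d", len(mols), len(rejections))
        chem_io.write_smiles_file(out / "standardized.smi", mols)
        rejections.write_tsv(out / "rejections.tsv")

        kind = config.fingerprint_kind
        logger.info("stage=fingerprint kind=%s", kind)
        fps = fingerprints.fingerprint_matrix(mols, kind)
        fp_df = pd.DataFrame(fps, columns=fingerprints.LABELS[kind])
        fp_df.insert(0, "id", [m.id for m in mols])
        fp_df.to_csv(out / "fingerprints.csv", index=False)

        logger.info("stage=pca d=%d", fps.shape[1])
        model = projection.fit_pca(fps)
        model.to_json(out / "model.json")
        coords = projection.project(model, fps, k=3)
        coords_df = pd.DataFrame(coords, columns=["pc1", "pc2", "pc3"])
        coords_df.insert(0, "id", [m.id for m in mols])
        coords_df.to_csv(out / "coords.csv", index=False)

        logger.info("stage=grid n_bins=%d", config.n_bins)
        grid = space3d.build_grid(coords, n_bins=config.n_bins)
        grid_doc = {
            "n_bins": grid.n_bins,
            "pc_min": grid.pc_min,
            "pc_max": grid.pc_max,
            "bin_size": grid.bin_size,
            "cells": [
                {"cell": list(cell), "members": members}
                for cell, members in sorted(grid.cells.items())
            ],
        }
        with open(out / "grid.json", "w") as fh:
            json.dump(grid_doc, fh, sort_keys=True)

        logger.info("stage=color descriptor=%s", config.descriptor)
        props = space3d.compute_properties(mols)
        colors = space3d.color_cells(grid, props, config.descriptor)

        overlay_points = []
        if config.overlay_path:
            logger.info("stage=overlay input=%s", config.overlay_path)
            overlay_log = chem_io.RejectionLog()
            overlay_records = chem_io.read_smiles_file(config.overlay_path, log=overlay_log)
            externals, overlay_log = chem_io.standardize_library(
                overlay_records, max_hac=config.max_hac, log=overlay_log
            )
            overlay_points = scene.overlay_external(model, grid, externals, kind)

        logger.info("stage=scene")
        sc = scene.build_scene(kind, grid, colors, mols, config.descriptor, overlay_points)
        scene.export_scene_json(sc, out / "scene.json")
        scene.export_html(sc, out / "scene.html")

        logger.info("stage=diagnostics")
        k_max = min(config.max_coverage_k, model.n_dims)
        coverage = {str(k): projection.variance_coverage(model, k) for k in range(1, k_max + 1)}
        try:
            dist_corr = projection.distance_correlation(
                coords, fps, n_pairs=config.n_pairs, seed=config.seed
            )
        except (projection.ZeroVarianceError, ValueError) as exc:
            logger.warning("distance correlation unavailable: %s", exc)
            dist_corr = None
        fp_vectors = [
            fingerprints.FingerprintVector(kind, row if kind != "sfp" else row.astype(np.uint8))
            for row in fps
        ]
        diagnostics = {
            "n_input": len(records),
            "n_standardized": len(mols),
            "n_rejected": len(rejections),
            "fingerprint_kind": kind,
            "variance_coverage": coverage,
            "distance_correlation_k3": dist_corr,
            "unique_fp_fraction": space3d.unique_fp_fraction(fp_vectors),
            "single_occupancy_3d": space3d.occupancy_stats(grid),
            "single_occupancy_2d": space3d.pixel_stats_2d(coords[:, :2], n_bins=config.n_bins),
            "seed": config.seed,
        }
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diagnostics, fh, sort_keys=True, indent=1)

        for name in (
            "standardized.smi", "rejections.tsv", "fingerprints.csv", "model.json",
            "coords.csv", "grid.json", "scene.json", "scene.html",
            "diagnostics.json", "run.log",
        ):
            artifacts[name] = str(out / name)
        logger.info("stage=done")
    finally:
        logger.removeHandler(handler)
        handler.close()

    return PipelineResult(
        mols=mols,
        rejections=rejections,
        fps=fps,
        model=model,
        coords=coords,
        grid=grid,
        scene=sc,
        diagnostics=diagnostics,
        artifacts=artifacts,
    )
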