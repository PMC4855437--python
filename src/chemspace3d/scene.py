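"""Scene assembly, overlays and serialization.

A Scene bundles the colored grid points of a library with optional
externally supplied overlay molecules projected into the SAME fitted
space (the stored PCA model and grid range are reused, never refit).
Scenes serialize losslessly to a single JSON document and to a
self-contained HTML viewer.
"""

from __future__ import annotations

import importlib.resources
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .chem_io import StandardizedMolecule
from .fingerprints import fingerprint_matrix
from .projection import PCAModel, project
from .space3d import CellColor, Grid3D

OVERLAY_LIMIT = 1000
OVERLAY_COLOR = (148, 0, 211)  # dark violet


class OverlayLimitError(ValueError):
    """Raised when more than OVERLAY_LIMIT external molecules are given."""


@dataclass
class ScenePoint:
    cell: tuple[int, int, int]
    rgb: tuple[int, int, int]
    member_ids: list[str]
    representative_smiles: str


@dataclass
class OverlayPoint:
    cell: tuple[int, int, int]
    id: str
    name: str
    rgb: tuple[int, int, int] = OVERLAY_COLOR


@dataclass
class Scene:
    fingerprint_kind: str
    n_bins: int
    pc_min: float
    pc_max: float
    bin_size: float
    descriptor: str
    points: list[ScenePoint] = field(default_factory=list)
    overlay_points: list[OverlayPoint] = field(default_factory=list)


def build_scene(
    kind: str,
    grid: Grid3D,
    colors: list[CellColor],
    mols: list[StandardizedMolecule],
    descriptor: str,
    overlay_points: list[OverlayPoint] | None = None,
) -> Scene:
    """Assemble a scene from a colored grid.

    The representative molecule of a multi-member cell is the member
    with the smallest source index (deterministic stand-in for showing
    an "average" structure, which is ill-defined).
    """
    color_by_cell = {c.cell: c.rgb for c in colors}
    points = []
    for cell in sorted(grid.cells.keys()):
        members = grid.cells[cell]
        rep = min(members, key=lambda i: mols[i].record.source_index)
        points.append(
            ScenePoint(
                cell=tuple(cell),
                rgb=color_by_cell.get(cell, (128, 128, 128)),
                member_ids=[mols[i].id for i in members],
                representative_smiles=mols[rep].canonical_smiles,
            )
        )
    return Scene(
        fingerprint_kind=kind,
        n_bins=grid.n_bins,
        pc_min=grid.pc_min,
        pc_max=grid.pc_max,
        bin_size=grid.bin_size,
        descriptor=descriptor,
        points=points,
        overlay_points=list(overlay_points or []),
    )


def overlay_external(
    model: PCAModel,
    grid: Grid3D,
    externals: list[StandardizedMolecule],
    kind: str,
) -> list[OverlayPoint]:
    """Project external molecules with the stored model and bin them
    with the stored grid range (out-of-range coordinates are clamped to
    the boundary cell)."""
    if len(externals) > OVERLAY_LIMIT:
        raise OverlayLimitError(
            f"{len(externals)} external molecules exceed the limit of {OVERLAY_LIMIT}"
        )
    if not externals:
        return []
    fps = fingerprint_matrix(externals, kind)
    coords = project(model, fps, k=3)
    return [
        OverlayPoint(cell=grid.cell_index(row, clamp=True), id=mol.id, name=mol.name)
        for mol, row in zip(externals, coords)
    ]


# ---------------------------------------------------------------------------
# Serialization


def scene_to_dict(scene: Scene) -> dict:
    return {
        "fingerprint_kind": scene.fingerprint_kind,
        "n_bins": int(scene.n_bins),
        "pc_min": scene.pc_min,
        "pc_max": scene.pc_max,
        "bin_size": scene.bin_size,
        "descriptor": scene.descriptor,
        "points": [
            {
                "cell": [int(v) for v in p.cell],
                "rgb": [int(v) for v in p.rgb],
                "member_ids": list(p.member_ids),
                "representative_smiles": p.representative_smiles,
            }
            for p in scene.points
        ],
        "overlay_points": [
            {
                "cell": [int(v) for v in p.cell],
                "rgb": [int(v) for v in p.rgb],
                "id": p.id,
                "name": p.name,
            }
            for p in scene.overlay_points
        ],
    }


def scene_from_dict(doc: dict) -> Scene:
    return Scene(
        fingerprint_kind=doc["fingerprint_kind"],
        n_bins=int(doc["n_bins"]),
        pc_min=float(doc["pc_min"]),
        pc_max=float(doc["pc_max"]),
        bin_size=float(doc["bin_size"]),
        descriptor=doc["descriptor"],
        points=[
            ScenePoint(
                cell=tuple(p["cell"]),
                rgb=tuple(p["rgb"]),
                member_ids=list(p["member_ids"]),
                representative_smiles=p["representative_smiles"],
            )
            for p in doc["points"]
        ],
        overlay_points=[
            OverlayPoint(
                cell=tuple(p["cell"]),
                rgb=tuple(p["rgb"]),
                id=p["id"],
                name=p["name"],
            )
            for p in doc["overlay_points"]
        ],
    )


def export_scene_json(scene: Scene, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(scene_to_dict(scene), fh, sort_keys=True)


def load_scene_json(path: str | os.PathLike) -> Scene:
    with open(path) as fh:
        return scene_from_dict(json.load(fh))


SCENE_PLACEHOLDER = "/*__SCENE_JSON__*/"


def export_html(scene: Scene, path: str | os.PathLike) -> None:
    """Write a self-contained HTML viewer with the scene JSON embedded.

    The viewer is a dependency-free canvas point-cloud renderer with
    drag rotation, wheel zoom and mouse-over id/SMILES display; opening
    the file requires no network access.
    """
    template = (
        importlib.resources.files("chemspace3d")
        .joinpath("viewer_template.html")
        .read_text()
    )
    doc = json.dumps(scene_to_dict(scene), sort_keys=True)
    with open(path, "w") as fh:
        fh.write(template.replace(SCENE_PLACEHOLDER, doc))
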