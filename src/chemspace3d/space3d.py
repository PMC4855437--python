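"""3D grid binning, occupancy diagnostics and HSL property coloring.

The grid covers the GLOBAL range of the first three principal
components: pc_min/pc_max are taken over all three axes jointly so the
bin size is the same absolute value on every axis. Hue encodes the cell
mean of a chosen descriptor along a blue-cyan-green-yellow-red-magenta
ramp; desaturation encodes the descriptor's spread in the +-radius cell
neighborhood.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import StandardizedMolecule
from .fingerprints import FingerprintVector, assign_categories, is_rotatable

DEFAULT_N_BINS = 300
DEFAULT_SATURATION_RADIUS = 5

HUE_MAX = 240.0  # blue, minimum property value
HUE_SPAN = 300.0  # down to -60 deg == 300 deg (magenta) at the maximum

PROPERTY_COLUMNS = (
    "ring_count",
    "aromatic_carbon_count",
    "rotatable_bond_count",
    "fraction_aromatic",
    "hba_count",
    "hac",
    "ncc_count",
)

# N-C=C; bond primitives also admit aromatic bonds so e.g. anilines match
_NCC_PATTERN = Chem.MolFromSmarts("[#7]-,:[#6]=,:[#6]")


@dataclass
class Grid3D:
    n_bins: int
    pc_min: float
    pc_max: float
    bin_size: float
    cells: dict[tuple[int, ...], list[int]] = field(default_factory=dict)

    @property
    def n_molecules(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def cell_index(self, coords: np.ndarray, clamp: bool = False) -> tuple[int, ...]:
        """Bin one coordinate row; ``clamp`` maps out-of-range values to
        the boundary cell (used for external overlays)."""
        coords = np.asarray(coords, dtype=float)
        if self.bin_size == 0:
            idx = np.zeros(len(coords), dtype=int)
        else:
            idx = np.floor((coords - self.pc_min) / self.bin_size).astype(int)
        if clamp:
            idx = np.clip(idx, 0, self.n_bins - 1)
        else:
            idx = np.minimum(idx, self.n_bins - 1)  # closed top edge
        return tuple(int(v) for v in idx)


def _build(coords: np.ndarray, n_bins: int, ndim: int) -> Grid3D:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != ndim:
        raise ValueError(f"coords must be (n, {ndim})")
    if len(coords) < 1:
        raise ValueError("need at least one molecule")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pc_min = float(coords.min())
    pc_max = float(coords.max())
    bin_size = (pc_max - pc_min) / n_bins
    grid = Grid3D(n_bins=n_bins, pc_min=pc_min, pc_max=pc_max, bin_size=bin_size)
    for i, row in enumerate(coords):
        grid.cells.setdefault(grid.cell_index(row), []).append(i)
    return grid


def build_grid(coords: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> Grid3D:
    """Bin (n, 3) PC coordinates onto an n_bins^3 grid with one global
    bin size; rows attaining pc_max land in index n_bins - 1."""
    return _build(coords, n_bins, ndim=3)


def occupancy_stats(grid: Grid3D) -> float:
    """Fraction of molecules residing in singly-occupied cells."""
    total = grid.n_molecules
    if total == 0:
        raise ValueError("empty grid")
    single = sum(1 for members in grid.cells.values() if len(members) == 1)
    return single / total


def unique_fp_fraction(fps) -> float:
    """Fraction of molecules whose exact fingerprint value combination
    occurs exactly once in the library."""
    if len(fps) == 0:
        raise ValueError("empty fingerprint list")
    keys = []
    for f in fps:
        values = f.values if isinstance(f, FingerprintVector) else np.asarray(f)
        keys.append(tuple(np.asarray(values).tolist()))
    counts: dict[tuple, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    return sum(1 for k in keys if counts[k] == 1) / len(keys)


def pixel_stats_2d(coords: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> float:
    """Single-occupancy fraction on a 2D pixel map built with the same
    global-range rule from (n, 2) coordinates."""
    return occupancy_stats(_build(coords, n_bins, ndim=2))


# ---------------------------------------------------------------------------
# Display properties


def compute_properties(mols: list[StandardizedMolecule]) -> pd.DataFrame:
    """Per-molecule display descriptors (PROPERTY_COLUMNS), one row per
    molecule in library order, indexed 0..n-1."""
    rows = []
    for mol in mols:
        m = mol.mol if isinstance(mol, StandardizedMolecule) else mol
        flags = assign_categories(m)
        hac = m.GetNumHeavyAtoms()
        aromatic_atoms = sum(1 for a in m.GetAtoms() if a.GetIsAromatic())
        rows.append(
            {
                "ring_count": m.GetRingInfo().NumRings(),
                "aromatic_carbon_count": sum(
                    1 for a in m.GetAtoms() if a.GetIsAromatic() and a.GetAtomicNum() == 6
                ),
                "rotatable_bond_count": sum(1 for b in m.GetBonds() if is_rotatable(b)),
                "fraction_aromatic": aromatic_atoms / hac if hac else 0.0,
                "hba_count": int(flags.hba.sum()),
                "hac": hac,
                "ncc_count": len(m.GetSubstructMatches(_NCC_PATTERN)),
            }
        )
    return pd.DataFrame(rows, columns=list(PROPERTY_COLUMNS))


# ---------------------------------------------------------------------------
# Coloring


@dataclass
class CellColor:
    cell: tuple[int, ...]
    mean_property: float
    local_std: float
    hue: float  # degrees in [0, 360)
    saturation: float
    lightness: float
    rgb: tuple[int, int, int]


def hsl_to_rgb(hue: float, saturation: float, lightness: float) -> tuple[int, int, int]:
    r, g, b = colorsys.hls_to_rgb((hue % 360.0) / 360.0, lightness, saturation)
    return (round(r * 255), round(g * 255), round(b * 255))


def color_cells(
    grid: Grid3D,
    props: pd.DataFrame,
    descriptor: str,
    radius: int = DEFAULT_SATURATION_RADIUS,
) -> list[CellColor]:
    """Color every occupied cell by the cell mean of ``descriptor``.

    hue = 240 - 300 * t (mod 360) with t the min-max normalized cell
    mean; saturation = 1 - min(1, local_std / global_std) where
    local_std is the population std over all molecules within +-radius
    cells in each direction (borders truncated).
    """
    if descriptor not in props.columns:
        raise KeyError(f"unknown descriptor {descriptor!r}")
    values = props[descriptor].to_numpy(dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    vspan = vmax - vmin
    global_std = float(values.std())  # population std

    occupied = sorted(grid.cells.keys())
    cell_set = set(occupied)
    out: list[CellColor] = []
    offsets = range(-radius, radius + 1)
    for cell in occupied:
        members = grid.cells[cell]
        mean_prop = float(values[members].mean())

        neighborhood: list[int] = []
        ci, cj, ck = cell
        for di in offsets:
            for dj in offsets:
                for dk in offsets:
                    key = (ci + di, cj + dj, ck + dk)
                    if key in cell_set:
                        neighborhood.extend(grid.cells[key])
        local_std = float(values[neighborhood].std())

        t = 0.0 if vspan == 0 else (mean_prop - vmin) / vspan
        hue = (HUE_MAX - HUE_SPAN * t) % 360.0
        saturation = 1.0 if global_std == 0 else 1.0 - min(1.0, local_std / global_std)
        out.append(
            CellColor(
                cell=cell,
                mean_property=mean_prop,
                local_std=local_std,
                hue=hue,
                saturation=saturation,
                lightness=0.5,
                rgb=hsl_to_rgb(hue, saturation, 0.5),
            )
        )
    return out
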