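"""Deterministic synthetic molecule libraries for testing every stage
without any external download.

Molecules are enumerated from chemically valid templates (alkanes,
cycloalkanes, decorated aromatics, polar aliphatics) so generation never
produces invalid structures except the explicitly planted rejects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

FAMILIES = ("alkanes", "rings", "aromatics", "polar")

_AROMATIC_CORES = ("c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccoc1", "c1ccsc1")
_AROMATIC_SUBS = (
    "C", "CC", "CCC", "O", "OC", "N", "CN", "Cl", "F", "Br",
    "C(=O)O", "C(=O)NC", "CCN", "CCO", "C#N", "S", "C(C)C", "OCC", "CNC", "C=C",
)
_POLAR_TEMPLATES = (
    "{chain}N", "{chain}NC", "{chain}N(C)C", "{chain}O", "{chain}OC",
    "{chain}C(=O)O", "{chain}C(=O)N", "{chain}C(=O)NC", "{chain}C(=O)OC",
    "NCC{chain}O", "OCC{chain}O", "{chain}S", "{chain}SC", "{chain}C#N",
    "{chain}NC(=O)C", "OC(=O)C{chain}C(=O)O",
)


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 100
    seed: int = 0
    families: tuple[str, ...] = FAMILIES
    min_hac: int = 2
    max_hac: int = 30
    n_duplicates: int = 0
    n_salts: int = 0
    n_invalid: int = 0
    n_oversized: int = 0  # planted > 50 heavy atom rejects


def make_alkane(n: int) -> str:
    """Linear alkane with n carbons."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return "C" * n


def _make_candidate(rng: np.random.Generator, family: str, spec: FixtureSpec) -> str:
    size = int(rng.integers(spec.min_hac, spec.max_hac + 1))
    if family == "alkanes":
        if size >= 4 and rng.random() < 0.5:
            return "CC(C)" + "C" * (size - 3)
        return make_alkane(size)
    if family == "rings":
        ring = int(rng.integers(3, 9))
        tail = max(0, min(size - ring, 10))
        return "C" * tail + "C1" + "C" * (ring - 2) + "C1"
    if family == "aromatics":
        core = _AROMATIC_CORES[int(rng.integers(len(_AROMATIC_CORES)))]
        n_subs = int(rng.integers(0, 3))
        smiles = core
        for _ in range(n_subs):
            smiles += _AROMATIC_SUBS[int(rng.integers(len(_AROMATIC_SUBS)))]
        return smiles
    if family == "polar":
        template = _POLAR_TEMPLATES[int(rng.integers(len(_POLAR_TEMPLATES)))]
        chain = "C" * int(rng.integers(1, max(2, spec.max_hac - 6)))
        return template.format(chain=chain)
    raise ValueError(f"unknown family {family!r}")


def make_library(spec: FixtureSpec) -> list[tuple[str, str]]:
    """Deterministic list of (smiles, name) pairs.

    The first ``n_molecules`` entries are pairwise distinct by canonical
    SMILES; planted duplicates, salt forms, oversized molecules and
    unparsable lines are appended afterwards so rejection counts are
    exact ground truth for the standardization pipeline.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > 200 * spec.n_molecules:
            raise RuntimeError("fixture template diversity exhausted for this spec")
        family = spec.families[int(rng.integers(len(spec.families)))]
        smiles = _make_candidate(rng, family, spec)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append((smiles, f"mol{len(out):05d}_{family}"))

    for i in range(spec.n_duplicates):
        src_smiles, src_name = out[i % spec.n_molecules]
        out.append((src_smiles, f"dup{i:03d}_of_{src_name}"))
    for i in range(spec.n_salts):
        src_smiles, src_name = out[i % spec.n_molecules]
        out.append((f"{src_smiles}.[Na+]", f"salt{i:03d}_of_{src_name}"))
    for i in range(spec.n_oversized):
        out.append((make_alkane(51 + i), f"oversized{i:03d}"))
    for i in range(spec.n_invalid):
        out.append((f"not_a_smiles_{i}", f"invalid{i:03d}"))
    return out


def write_library(path: str | os.PathLike, library: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for smiles, name in library:
            fh.write(f"{smiles} {name}\n")
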