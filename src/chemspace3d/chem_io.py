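"""Reading and standardization of small-molecule libraries.

Input formats are V2000 SDF and plain SMILES text ("SMILES name" per
line). Standardization applies, in order: a valence check (delegated to
RDKit sanitization), counterion removal (keep the largest fragment),
rule-based charge adjustment approximating physiological pH, and a
heavy-atom-count ceiling. Deduplication uses the post-standardization
canonical SMILES (stereo-aware) as identity key.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

DEFAULT_MAX_HAC = 50

REASON_PARSE = "parse_error"
REASON_VALENCE = "valence_error"
REASON_TOO_LARGE = "too_large"
REASON_DUPLICATE = "duplicate"
REASON_EMPTY = "empty_after_saltstrip"

_REASONS = frozenset(
    {REASON_PARSE, REASON_VALENCE, REASON_TOO_LARGE, REASON_DUPLICATE, REASON_EMPTY}
)


class EmptyLibraryError(ValueError):
    """Raised when an input file yields zero parsable molecules."""


@dataclass
class MoleculeRecord:
    """One parsed (possibly unsanitized) molecule from an input library."""

    id: str
    name: str
    smiles_input: str
    mol: Chem.Mol
    source_index: int


@dataclass
class StandardizedMolecule:
    """A molecule that survived standardization.

    ``canonical_smiles`` is recomputed after all transformations and is
    the deduplication key; ``hac`` is the heavy-atom count.
    """

    record: MoleculeRecord
    canonical_smiles: str
    hac: int
    mol: Chem.Mol

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def name(self) -> str:
        return self.record.name


@dataclass
class RejectionLog:
    """Accumulates (id, reason) pairs for every rejected input record."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, mol_id: str, reason: str) -> None:
        if reason not in _REASONS:
            raise ValueError(f"unknown rejection reason {reason!r}")
        self.entries.append((mol_id, reason))

    def __len__(self) -> int:
        return len(self.entries)

    def count(self, reason: str) -> int:
        return sum(1 for _, r in self.entries if r == reason)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("id\treason\n")
            for mol_id, reason in self.entries:
                fh.write(f"{mol_id}\t{reason}\n")


# ---------------------------------------------------------------------------
# Reading


def read_sdf(path: str | os.PathLike, log: Optional[RejectionLog] = None) -> list[MoleculeRecord]:
    """Read a V2000 SDF into records, skipping (and logging) corrupt blocks.

    Sanitization is deferred to :func:`standardize` so that valence
    problems are reported as ``valence_error`` rather than silently
    dropped here.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    log = log if log is not None else RejectionLog()
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    except OSError as exc:
        raise EmptyLibraryError(f"no parsable molecule blocks in {path}: {exc}") from exc
    records: list[MoleculeRecord] = []
    source_index = 0
    for block_no, mol in enumerate(supplier):
        if mol is None:
            log.add(f"sdf_block{block_no}", REASON_PARSE)
            continue
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not name:
            name = f"mol{block_no}"
        try:
            smiles = Chem.MolToSmiles(mol)
        except Exception:
            smiles = ""
        records.append(
            MoleculeRecord(
                id=name,
                name=name,
                smiles_input=smiles,
                mol=mol,
                source_index=source_index,
            )
        )
        source_index += 1
    if not records:
        raise EmptyLibraryError(f"no parsable molecule blocks in {path}")
    return records


def read_smiles_file(
    path: str | os.PathLike, log: Optional[RejectionLog] = None
) -> list[MoleculeRecord]:
    """Read a "SMILES name" text file; '#'-prefixed lines are comments.

    The name is everything after the first space; unnamed molecules get
    an auto-assigned ``mol<k>`` name. Unparsable lines are logged, not
    fatal.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = fh.readlines()
    return parse_smiles_lines(lines, log=log, origin=str(path))


def parse_smiles_lines(
    lines: Iterable[str],
    log: Optional[RejectionLog] = None,
    origin: str = "<lines>",
) -> list[MoleculeRecord]:
    log = log if log is not None else RejectionLog()
    records: list[MoleculeRecord] = []
    source_index = 0
    for line_no, raw in enumerate(lines):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        smiles, _, rest = line.partition(" ")
        name = rest.strip() or f"mol{line_no}"
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if mol is None or mol.GetNumAtoms() == 0:
            log.add(name, REASON_PARSE)
            continue
        records.append(
            MoleculeRecord(
                id=name,
                name=name,
                smiles_input=smiles,
                mol=mol,
                source_index=source_index,
            )
        )
        source_index += 1
    if not records:
        raise EmptyLibraryError(f"no parsable molecules in {origin}")
    return records


# ---------------------------------------------------------------------------
# pH 7.4 charge rules
#
# Deterministic rule-based approximation: deprotonate carboxylic,
# sulfonic and sulfinic acids, one proton per phosphate/phosphonate
# group, and tetrazole NH; protonate aliphatic amines (not amides,
# anilines, sulfonamides or aromatic N), amidines and guanidines at the
# sp2 nitrogen.

_DEPROTONATE_O = [
    Chem.MolFromSmarts("[OX2H1][CX3]=[OX1]"),  # carboxylic acid
    Chem.MolFromSmarts("[OX2H1][SX4](=[OX1])=[OX1]"),  # sulfonic acid
    Chem.MolFromSmarts("[OX2H1][SX3]=[OX1]"),  # sulfinic acid
]
_PHOSPHORUS = Chem.MolFromSmarts("[PX4](=[OX1])[OX2H1]")
_TETRAZOLE_NH = [
    Chem.MolFromSmarts("[nX3H1]1nnnc1"),
    Chem.MolFromSmarts("[nX3H1]1nncn1"),
]
_AMIDINE_N = Chem.MolFromSmarts("[NX2;+0;!$(N-[!#6;!#1])]=[CX3;!$(C-[OX2])]-[NX3;+0]")
_ALIPHATIC_AMINE = Chem.MolFromSmarts(
    "[NX3;+0;!$(N=*);!$(N#*);!$(N-[a]);"
    "!$(N-[#6X3]=[OX1]);!$(N-[#6X3]=[SX1]);!$(N-[#6X3]=[#7]);"
    "!$(N-[SX4]);!$(N-[SX3]);!$(N-[PX4]);!$(N-[O]);!$(N-[N])]"
)


def _deprotonate(atom: Chem.Atom) -> None:
    atom.SetFormalCharge(atom.GetFormalCharge() - 1)
    atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() - 1))
    atom.SetNoImplicit(True)


def _protonate(atom: Chem.Atom) -> None:
    atom.SetFormalCharge(atom.GetFormalCharge() + 1)
    atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
    atom.SetNoImplicit(True)


def apply_ph74_rules(mol: Chem.Mol) -> Chem.Mol:
    """Apply the rule-based charge adjustments in place on a copy."""
    rw = Chem.RWMol(mol)

    for patt in _DEPROTONATE_O:
        for match in rw.GetSubstructMatches(patt):
            _deprotonate(rw.GetAtomWithIdx(match[0]))

    # one proton per phosphate/phosphonate group: the lowest-index P-OH;
    # skipped when the group already carries an anionic oxygen
    seen_p: set[int] = set()
    for match in rw.GetSubstructMatches(_PHOSPHORUS):
        p_idx, _, o_idx = match
        if p_idx in seen_p:
            continue
        seen_p.add(p_idx)
        p_atom = rw.GetAtomWithIdx(p_idx)
        if any(
            nb.GetAtomicNum() == 8 and nb.GetFormalCharge() < 0
            for nb in p_atom.GetNeighbors()
        ):
            continue
        _deprotonate(rw.GetAtomWithIdx(o_idx))

    for patt in _TETRAZOLE_NH:
        for match in rw.GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[0])
            if atom.GetFormalCharge() == 0:
                _deprotonate(atom)

    # each basic nitrogen protonated at most once even when matched by
    # several symmetric substructure embeddings (e.g. guanidine)
    basic_n: list[int] = []
    for match in rw.GetSubstructMatches(_AMIDINE_N):
        basic_n.append(match[0])
    for match in rw.GetSubstructMatches(_ALIPHATIC_AMINE):
        basic_n.append(match[0])
    for idx in dict.fromkeys(basic_n):
        _protonate(rw.GetAtomWithIdx(idx))

    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _pick_fragment(frags: tuple[Chem.Mol, ...]) -> Chem.Mol:
    """Largest fragment by HAC; ties: higher mass, then smallest SMILES."""

    def key(frag: Chem.Mol):
        return (
            -frag.GetNumHeavyAtoms(),
            -Descriptors.MolWt(frag),
            Chem.MolToSmiles(frag),
        )

    return min(frags, key=key)


# ---------------------------------------------------------------------------
# Standardization


def standardize(
    record: MoleculeRecord,
    max_hac: int = DEFAULT_MAX_HAC,
    log: Optional[RejectionLog] = None,
) -> Optional[StandardizedMolecule]:
    """Standardize one record; returns ``None`` (logged) on rejection."""
    log = log if log is not None else RejectionLog()
    mol = Chem.Mol(record.mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        log.add(record.id, REASON_VALENCE)
        return None

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        log.add(record.id, REASON_EMPTY)
        return None
    kept = _pick_fragment(frags)
    if kept.GetNumHeavyAtoms() == 0:
        log.add(record.id, REASON_EMPTY)
        return None

    try:
        kept = apply_ph74_rules(kept)
    except Exception:
        log.add(record.id, REASON_VALENCE)
        return None

    hac = kept.GetNumHeavyAtoms()
    if hac > max_hac:
        log.add(record.id, REASON_TOO_LARGE)
        return None

    return StandardizedMolecule(
        record=record,
        canonical_smiles=Chem.MolToSmiles(kept),
        hac=hac,
        mol=kept,
    )


def deduplicate(
    mols: list[StandardizedMolecule], log: Optional[RejectionLog] = None
) -> list[StandardizedMolecule]:
    """Keep the first occurrence per canonical SMILES, preserving order."""
    log = log if log is not None else RejectionLog()
    seen: set[str] = set()
    kept: list[StandardizedMolecule] = []
    for mol in mols:
        if mol.canonical_smiles in seen:
            log.add(mol.id, REASON_DUPLICATE)
            continue
        seen.add(mol.canonical_smiles)
        kept.append(mol)
    return kept


def standardize_library(
    records: list[MoleculeRecord],
    max_hac: int = DEFAULT_MAX_HAC,
    log: Optional[RejectionLog] = None,
) -> tuple[list[StandardizedMolecule], RejectionLog]:
    """Standardize and deduplicate a whole library.

    Guarantees ``len(records) == len(result) + len(log)`` (for the
    entries added during this call).
    """
    log = log if log is not None else RejectionLog()
    standardized = []
    for record in records:
        out = standardize(record, max_hac=max_hac, log=log)
        if out is not None:
            standardized.append(out)
    return deduplicate(standardized, log=log), log


def standardize_smiles(smiles: str, max_hac: int = DEFAULT_MAX_HAC) -> StandardizedMolecule:
    """Convenience: parse + standardize a single SMILES; raises on rejection."""
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    record = MoleculeRecord(id=smiles, name=smiles, smiles_input=smiles, mol=mol, source_index=0)
    log = RejectionLog()
    out = standardize(record, max_hac=max_hac, log=log)
    if out is None:
        raise ValueError(f"rejected ({log.entries[-1][1]}): {smiles!r}")
    return out


def write_smiles_file(path: str | os.PathLike, mols: list[StandardizedMolecule]) -> None:
    """Write a standardized library back out as "SMILES name" lines."""
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{mol.canonical_smiles} {mol.name}\n")
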