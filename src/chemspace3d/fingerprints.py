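"""Five molecular fingerprints and their distance metrics.

Scalar fingerprints
    mqn    42 integer counts of atom types, bond types, polar groups and
           topological features.
    smifp  34 character counts over a fixed alphabet applied to the
           canonical SMILES.
    apfp   20 heavy-atom-pair counts by topological distance 1-20 bonds,
           normalized to the heavy-atom count (molecular shape).
    xfp    55 = 5 category blocks x 11 distances (0-10 bonds) of
           pharmacophore-category atom pairs, normalized per block
           (pharmacophore).

Binary fingerprint
    sfp    1024-bit hashed linear-path substructure fingerprint
           (paths of 1-7 bonds, 2 bits per path).

All fingerprints are computed on the canonically renumbered molecular
graph so they are invariant to input atom ordering. Scalar fingerprints
are compared with the city-block distance, the binary fingerprint with
the Tanimoto coefficient.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import HybridizationType

from .chem_io import StandardizedMolecule, standardize_smiles

KIND_LENGTHS = {"mqn": 42, "smifp": 34, "apfp": 20, "xfp": 55, "sfp": 1024}
SCALAR_KINDS = ("mqn", "smifp", "apfp", "xfp")

APFP_MAX_DIST = 20
XFP_MAX_DIST = 10
XFP_CATEGORIES = ("hydrophobic", "hbd", "hba", "sp2", "hba_hbd")

SFP_MIN_PATH = 1
SFP_MAX_PATH = 7
SFP_N_BITS = 1024
SFP_BITS_PER_HASH = 2


class FingerprintKindError(ValueError):
    """Raised when fingerprint kinds are mixed or unknown."""


@dataclass(frozen=True)
class FingerprintVector:
    kind: str
    values: np.ndarray

    def __post_init__(self):
        if self.kind not in KIND_LENGTHS:
            raise FingerprintKindError(f"unknown fingerprint kind {self.kind!r}")
        if len(self.values) != KIND_LENGTHS[self.kind]:
            raise FingerprintKindError(
                f"{self.kind} vector must have {KIND_LENGTHS[self.kind]} "
                f"components, got {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AtomCategoryFlags:
    """Per-heavy-atom pharmacophore category membership."""

    hydrophobic: np.ndarray
    hbd: np.ndarray
    hba: np.ndarray
    sp2: np.ndarray


def _as_mol(mol) -> Chem.Mol:
    """Coerce input to a canonically ordered RDKit molecule."""
    if isinstance(mol, StandardizedMolecule):
        smiles = mol.canonical_smiles
    elif isinstance(mol, Chem.Mol):
        smiles = Chem.MolToSmiles(mol)
    elif isinstance(mol, str):
        smiles = standardize_smiles(mol).canonical_smiles
    else:
        raise TypeError(f"cannot interpret {type(mol)} as a molecule")
    out = Chem.MolFromSmiles(smiles)
    if out is None:
        raise ValueError(f"canonical SMILES failed to re-parse: {smiles!r}")
    return out


def _heavy_degree(atom: Chem.Atom) -> int:
    return sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)


def is_rotatable(bond: Chem.Bond) -> bool:
    """Acyclic single bond between two non-terminal heavy atoms, amide
    C-N excluded."""
    if bond.IsInRing() or bond.GetIsAromatic():
        return False
    if bond.GetBondType() != Chem.BondType.SINGLE:
        return False
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    if _heavy_degree(a) < 2 or _heavy_degree(b) < 2:
        return False
    for c_atom, n_atom in ((a, b), (b, a)):
        if c_atom.GetAtomicNum() == 6 and n_atom.GetAtomicNum() == 7:
            for nb_bond in c_atom.GetBonds():
                other = nb_bond.GetOtherAtom(c_atom)
                if other.GetAtomicNum() == 8 and nb_bond.GetBondType() == Chem.BondType.DOUBLE:
                    return False
    return True


# ---------------------------------------------------------------------------
# MQN

MQN_LABELS = [
    # atom counts (12)
    "c", "f", "cl", "br", "i", "s", "p", "an", "cn", "ao", "co", "hac",
    # bond counts (7)
    "asb", "adb", "atb", "csb", "cdb", "ctb", "rbc",
    # polarity (6)
    "hbam", "hba", "hbdm", "hbd", "neg", "pos",
    # topology (17)
    "asv", "adv", "atv", "aqv", "cdv", "ctv", "cqv",
    "r3", "r4", "r5", "r6", "r7", "r8", "r9", "rg10", "afr", "bfr",
]

# lone pairs available on neutral acceptor atoms; anionic charge adds one
_LONE_PAIRS = {7: 1, 8: 2}


def mqn(mol) -> FingerprintVector:
    """42 molecular quantum numbers in the fixed MQN_LABELS order.

    Bond-type counts are taken on one deterministic Kekule structure of
    the canonically ordered graph; ring descriptors use SSSR.
    """
    m = _as_mol(mol)
    counts = dict.fromkeys(MQN_LABELS, 0)

    flags = assign_categories(m)

    for atom in m.GetAtoms():
        z = atom.GetAtomicNum()
        in_ring = atom.IsInRing()
        if z > 1:
            counts["hac"] += 1
        if z == 6:
            counts["c"] += 1
        elif z == 9:
            counts["f"] += 1
        elif z == 17:
            counts["cl"] += 1
        elif z == 35:
            counts["br"] += 1
        elif z == 53:
            counts["i"] += 1
        elif z == 16:
            counts["s"] += 1
        elif z == 15:
            counts["p"] += 1
        elif z == 7:
            counts["cn" if in_ring else "an"] += 1
        elif z == 8:
            counts["co" if in_ring else "ao"] += 1

        charge = atom.GetFormalCharge()
        if charge < 0:
            counts["neg"] += -charge
        elif charge > 0:
            counts["pos"] += charge

        idx = atom.GetIdx()
        if flags.hbd[idx]:
            counts["hbd"] += 1
            counts["hbdm"] += atom.GetTotalNumHs()
        if flags.hba[idx]:
            counts["hba"] += 1
            counts["hbam"] += _LONE_PAIRS.get(z, 1) + max(0, -charge)

        deg = _heavy_degree(atom)
        if z > 1:
            if not in_ring:
                if deg == 1:
                    counts["asv"] += 1
                elif deg == 2:
                    counts["adv"] += 1
                elif deg == 3:
                    counts["atv"] += 1
                elif deg >= 4:
                    counts["aqv"] += 1
            else:
                if deg == 2:
                    counts["cdv"] += 1
                elif deg == 3:
                    counts["ctv"] += 1
                elif deg >= 4:
                    counts["cqv"] += 1

    # bond counts on the Kekule structure
    kek = Chem.Mol(m)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    for bond in kek.GetBonds():
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        order = bond.GetBondType()
        in_ring = bond.IsInRing()
        if order == Chem.BondType.SINGLE:
            counts["csb" if in_ring else "asb"] += 1
        elif order == Chem.BondType.DOUBLE:
            counts["cdb" if in_ring else "adb"] += 1
        elif order == Chem.BondType.TRIPLE:
            counts["ctb" if in_ring else "atb"] += 1
    counts["rbc"] = sum(1 for b in m.GetBonds() if is_rotatable(b))

    # SSSR ring descriptors
    ring_info = m.GetRingInfo()
    atom_membership = dict.fromkeys(range(m.GetNumAtoms()), 0)
    bond_membership = dict.fromkeys(range(m.GetNumBonds()), 0)
    for ring_atoms in ring_info.AtomRings():
        size = len(ring_atoms)
        if 3 <= size <= 9:
            counts[f"r{size}"] += 1
        else:
            counts["rg10"] += 1
        for a in ring_atoms:
            atom_membership[a] += 1
    for ring_bonds in ring_info.BondRings():
        for b in ring_bonds:
            bond_membership[b] += 1
    counts["afr"] = sum(1 for v in atom_membership.values() if v >= 2)
    counts["bfr"] = sum(1 for v in bond_membership.values() if v >= 2)

    return FingerprintVector("mqn", np.array([counts[k] for k in MQN_LABELS], dtype=np.int64))


# ---------------------------------------------------------------------------
# SMIfp

SMIFP_ALPHABET = (
    "C", "c", "N", "n", "O", "o", "S", "s", "P", "F", "Cl", "Br", "I", "B",
    "=", "#", "(", "[", "+", "-", ".", "@", "/", "\\", "%",
    "1", "2", "3", "4", "5", "6", "7", "8", "9",
)

_SMIFP_TWO_CHAR = ("Cl", "Br")
_SMIFP_SINGLE = frozenset(s for s in SMIFP_ALPHABET if len(s) == 1)


def smifp(canonical_smiles) -> FingerprintVector:
    """Character counts of a canonical SMILES over the 34-symbol alphabet.

    Two-letter element symbols consume both characters; the two digits
    of a %nn ring closure are not counted as ring digits; ')' and ']'
    are redundant with their openers and not counted.
    """
    if isinstance(canonical_smiles, str):
        s = canonical_smiles
    else:
        s = Chem.MolToSmiles(_as_mol(canonical_smiles))
    counts = dict.fromkeys(SMIFP_ALPHABET, 0)
    i = 0
    while i < len(s):
        if s[i : i + 2] in _SMIFP_TWO_CHAR:
            counts[s[i : i + 2]] += 1
            i += 2
            continue
        ch = s[i]
        if ch == "%":
            counts["%"] += 1
            i += 3  # skip the two-digit ring closure label
            continue
        if ch in _SMIFP_SINGLE:
            counts[ch] += 1
        i += 1
    return FingerprintVector(
        "smifp", np.array([counts[k] for k in SMIFP_ALPHABET], dtype=np.int64)
    )


# ---------------------------------------------------------------------------
# APfp

APFP_LABELS = [f"d{d}" for d in range(1, APFP_MAX_DIST + 1)]


def apfp(mol) -> FingerprintVector:
    """Heavy-atom pair counts per topological distance 1-20, / HAC.

    Pairs farther apart than 20 bonds are dropped.
    """
    m = _as_mol(mol)
    hac = m.GetNumHeavyAtoms()
    values = np.zeros(APFP_MAX_DIST, dtype=np.float64)
    if hac >= 2:
        dm = Chem.GetDistanceMatrix(m)
        iu = np.triu_indices(hac, k=1)
        dists = dm[iu]
        for d in range(1, APFP_MAX_DIST + 1):
            values[d - 1] = np.count_nonzero(dists == d)
    if hac >= 1:
        values /= hac
    return FingerprintVector("apfp", values)


# ---------------------------------------------------------------------------
# Xfp

XFP_LABELS = [
    f"{cat}_d{d}" for cat in XFP_CATEGORIES for d in range(XFP_MAX_DIST + 1)
]


def assign_categories(mol) -> AtomCategoryFlags:
    """Pharmacophore category flags for every atom.

    hydrophobic: carbon or halogen with no N/O neighbor.
    hbd: N or O bearing at least one hydrogen.
    hba: N or O accepting; excludes pyrrole-type aromatic N (no free
    in-plane lone pair), amide N and positively charged atoms.
    sp2: sp2-hybridized, aromatic atoms included.
    """
    m = mol if isinstance(mol, Chem.Mol) else _as_mol(mol)
    n = m.GetNumAtoms()
    hydrophobic = np.zeros(n, dtype=bool)
    hbd = np.zeros(n, dtype=bool)
    hba = np.zeros(n, dtype=bool)
    sp2 = np.zeros(n, dtype=bool)
    for atom in m.GetAtoms():
        idx = atom.GetIdx()
        z = atom.GetAtomicNum()
        if z in (6, 9, 17, 35, 53) and not any(
            nb.GetAtomicNum() in (7, 8) for nb in atom.GetNeighbors()
        ):
            hydrophobic[idx] = True
        if z in (7, 8):
            if atom.GetTotalNumHs() >= 1:
                hbd[idx] = True
            accepts = atom.GetFormalCharge() <= 0
            if z == 7:
                if atom.GetIsAromatic() and _heavy_degree(atom) + atom.GetTotalNumHs() >= 3:
                    accepts = False  # pyrrole-type N
                for bond in atom.GetBonds():
                    other = bond.GetOtherAtom(atom)
                    if other.GetAtomicNum() == 6:
                        for cb in other.GetBonds():
                            if (
                                cb.GetBondType() == Chem.BondType.DOUBLE
                                and cb.GetOtherAtom(other).GetAtomicNum() == 8
                            ):
                                accepts = False  # amide N
            if accepts:
                hba[idx] = True
        if atom.GetIsAromatic() or atom.GetHybridization() == HybridizationType.SP2:
            sp2[idx] = True
    return AtomCategoryFlags(hydrophobic=hydrophobic, hbd=hbd, hba=hba, sp2=sp2)


def xfp(mol) -> FingerprintVector:
    """Category atom-pair counts at distances 0-10 bonds, normalized per
    block to the number of category atoms.

    Same-category blocks count unordered pairs (d=0: each category atom
    once as a self-pair). The acceptor/donor cross block counts each
    unordered mixed pair once (d=0: atoms that are both acceptor and
    donor) and normalizes by |hba or hbd|. Empty blocks are all-zero.
    """
    m = _as_mol(mol)
    flags = assign_categories(m)
    n = m.GetNumAtoms()
    dm = Chem.GetDistanceMatrix(m) if n >= 2 else np.zeros((n, n))

    values = np.zeros(len(XFP_CATEGORIES) * (XFP_MAX_DIST + 1), dtype=np.float64)

    for block, cat in enumerate(("hydrophobic", "hbd", "hba", "sp2")):
        members = np.flatnonzero(getattr(flags, cat))
        base = block * (XFP_MAX_DIST + 1)
        n_cat = len(members)
        if n_cat == 0:
            continue
        values[base + 0] = n_cat  # self-pairs
        for a_pos in range(n_cat):
            for b_pos in range(a_pos + 1, n_cat):
                d = int(dm[members[a_pos], members[b_pos]])
                if 1 <= d <= XFP_MAX_DIST:
                    values[base + d] += 1
        values[base : base + XFP_MAX_DIST + 1] /= n_cat

    base = 4 * (XFP_MAX_DIST + 1)
    union = np.flatnonzero(flags.hba | flags.hbd)
    if len(union):
        values[base + 0] = np.count_nonzero(flags.hba & flags.hbd)
        for a_pos in range(len(union)):
            for b_pos in range(a_pos + 1, len(union)):
                a, b = union[a_pos], union[b_pos]
                if (flags.hba[a] and flags.hbd[b]) or (flags.hbd[a] and flags.hba[b]):
                    d = int(dm[a, b])
                    if 1 <= d <= XFP_MAX_DIST:
                        values[base + d] += 1
        values[base : base + XFP_MAX_DIST + 1] /= len(union)

    return FingerprintVector("xfp", values)


# ---------------------------------------------------------------------------
# Sfp

SFP_LABELS = [f"b{i}" for i in range(SFP_N_BITS)]


def sfp(mol) -> FingerprintVector:
    """1024-bit hashed linear-path substructure fingerprint (1-7 bonds).

    Bond-less molecules (single heavy atoms) have no paths; their atoms
    are hashed directly so the fingerprint is never empty.
    """
    m = _as_mol(mol)
    bv = Chem.RDKFingerprint(
        m,
        minPath=SFP_MIN_PATH,
        maxPath=SFP_MAX_PATH,
        fpSize=SFP_N_BITS,
        nBitsPerHash=SFP_BITS_PER_HASH,
    )
    values = np.zeros(SFP_N_BITS, dtype=np.uint8)
    for bit in bv.GetOnBits():
        values[bit] = 1
    if m.GetNumBonds() == 0:
        for atom in m.GetAtoms():
            seed = zlib.crc32(f"atom:{atom.GetSymbol()}{atom.GetFormalCharge():+d}".encode())
            for i in range(SFP_BITS_PER_HASH):
                values[zlib.crc32(str(i).encode(), seed) % SFP_N_BITS] = 1
    return FingerprintVector("sfp", values)


# ---------------------------------------------------------------------------
# Metrics and batch helpers

COMPUTERS = {"mqn": mqn, "smifp": smifp, "apfp": apfp, "xfp": xfp, "sfp": sfp}
LABELS = {
    "mqn": MQN_LABELS,
    "smifp": list(SMIFP_ALPHABET),
    "apfp": APFP_LABELS,
    "xfp": XFP_LABELS,
    "sfp": SFP_LABELS,
}


def compute(kind: str, mol) -> FingerprintVector:
    if kind not in COMPUTERS:
        raise FingerprintKindError(f"unknown fingerprint kind {kind!r}")
    return COMPUTERS[kind](mol)


def fingerprint_matrix(mols, kind: str) -> np.ndarray:
    """Stack fingerprints of ``mols`` into an (n, D) float matrix."""
    return np.array([compute(kind, m).values for m in mols], dtype=np.float64)


def cbd(u: FingerprintVector, v: FingerprintVector) -> float:
    """City-block distance between two scalar fingerprints."""
    if u.kind != v.kind:
        raise FingerprintKindError(f"kind mismatch: {u.kind} vs {v.kind}")
    if u.kind not in SCALAR_KINDS:
        raise FingerprintKindError(f"city-block distance undefined for {u.kind}")
    return float(np.abs(np.asarray(u.values, dtype=float) - np.asarray(v.values, dtype=float)).sum())


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto coefficient of two binary fingerprints; 1.0 when both empty."""
    if a.kind != b.kind:
        raise FingerprintKindError(f"kind mismatch: {a.kind} vs {b.kind}")
    if a.kind != "sfp":
        raise FingerprintKindError(f"Tanimoto defined for sfp only, got {a.kind}")
    av = np.asarray(a.values, dtype=bool)
    bv = np.asarray(b.values, dtype=bool)
    union = np.count_nonzero(av | bv)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(av & bv) / union)
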