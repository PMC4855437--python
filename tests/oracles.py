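"""Independent brute-force oracles used by the tests.

Shortest-path distances are computed with networkx BFS over the bond
graph, independently of the main implementation's distance matrix, and
pairs are enumerated naively.
"""

import networkx as nx
import numpy as np
from rdkit import Chem

from chemspace3d.fingerprints import (
    APFP_MAX_DIST,
    XFP_MAX_DIST,
    assign_categories,
)


def bond_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return g


def topo_distances(mol: Chem.Mol) -> dict:
    return dict(nx.all_pairs_shortest_path_length(bond_graph(mol)))


def apfp_oracle(mol: Chem.Mol) -> np.ndarray:
    dist = topo_distances(mol)
    n = mol.GetNumAtoms()
    values = np.zeros(APFP_MAX_DIST)
    for a in range(n):
        for b in range(a + 1, n):
            d = dist[a].get(b)
            if d is not None and 1 <= d <= APFP_MAX_DIST:
                values[d - 1] += 1
    return values / n if n else values


def xfp_oracle(mol: Chem.Mol) -> np.ndarray:
    dist = topo_distances(mol)
    flags = assign_categories(mol)
    n = mol.GetNumAtoms()
    width = XFP_MAX_DIST + 1
    values = np.zeros(5 * width)

    for block, mask in enumerate([flags.hydrophobic, flags.hbd, flags.hba, flags.sp2]):
        members = [i for i in range(n) if mask[i]]
        if not members:
            continue
        base = block * width
        values[base] = len(members)
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                d = dist[members[ai]].get(members[bi])
                if d is not None and 1 <= d <= XFP_MAX_DIST:
                    values[base + d] += 1
        values[base : base + width] /= len(members)

    union = [i for i in range(n) if flags.hba[i] or flags.hbd[i]]
    if union:
        base = 4 * width
        values[base] = sum(1 for i in union if flags.hba[i] and flags.hbd[i])
        for ai in range(len(union)):
            for bi in range(ai + 1, len(union)):
                a, b = union[ai], union[bi]
                if (flags.hba[a] and flags.hbd[b]) or (flags.hbd[a] and flags.hba[b]):
                    d = dist[a].get(b)
                    if d is not None and 1 <= d <= XFP_MAX_DIST:
                        values[base + d] += 1
        values[base : base + width] /= len(union)
    return values
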