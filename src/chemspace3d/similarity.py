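"""Exact nearest-neighbor search in the original fingerprint spaces.

Scalar fingerprints rank ascending by city-block distance, the binary
substructure fingerprint descending by Tanimoto coefficient. The scan is
exhaustive and ties are broken by library insertion order, so results
are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fingerprints import FingerprintKindError, FingerprintVector, SCALAR_KINDS


@dataclass
class NeighborEntry:
    index: int
    id: str
    score: float  # distance (scalar kinds) or similarity (sfp)


@dataclass
class NeighborList:
    query_id: str
    kind: str
    metric: str
    entries: list[NeighborEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def nearest_neighbors(
    query: FingerprintVector,
    library: list[FingerprintVector],
    k: int = 10,
    ids: list[str] | None = None,
    query_id: str = "query",
) -> NeighborList:
    """Top-k exact neighbors of ``query`` in ``library``."""
    if not library:
        raise ValueError("empty library")
    if k < 1:
        raise ValueError("k must be >= 1")
    kind = query.kind
    for fp in library:
        if fp.kind != kind:
            raise FingerprintKindError(f"kind mismatch: {fp.kind} vs {kind}")
    if ids is None:
        ids = [str(i) for i in range(len(library))]

    lib = np.asarray([fp.values for fp in library], dtype=float)
    q = np.asarray(query.values, dtype=float)

    if kind in SCALAR_KINDS:
        metric = "cityblock"
        scores = np.abs(lib - q).sum(axis=1)
        order = np.argsort(scores, kind="stable")
    elif kind == "sfp":
        metric = "tanimoto"
        qb = q.astype(bool)
        lb = lib.astype(bool)
        inter = (lb & qb).sum(axis=1)
        union = (lb | qb).sum(axis=1)
        scores = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
        order = np.argsort(-scores, kind="stable")
    else:  # pragma: no cover - kinds are exhaustive
        raise FingerprintKindError(f"no metric for kind {kind!r}")

    entries = [
        NeighborEntry(index=int(i), id=ids[int(i)], score=float(scores[int(i)]))
        for i in order[:k]
    ]
    return NeighborList(query_id=query_id, kind=kind, metric=metric, entries=entries)


def write_neighbors_tsv(path, neighbors: NeighborList) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tid\t%s\n" % ("distance" if neighbors.metric == "cityblock" else "similarity"))
        for rank, entry in enumerate(neighbors.entries, start=1):
            fh.write(f"{rank}\t{entry.id}\t{entry.score:.6g}\n")
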