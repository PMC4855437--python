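"""PCA of fingerprint matrices and projection diagnostics.

Covariance-eigendecomposition PCA without unit-variance scaling (raw
counts), with an optional scaling flag. The fitted model is serializable
to JSON so external molecules can be projected into a previously fitted
space.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist


class ZeroVarianceError(ValueError):
    """Raised when a distance correlation is undefined (zero spread)."""


@dataclass
class PCAModel:
    means: np.ndarray  # (D,)
    loadings: np.ndarray  # (D, D) orthonormal columns, eigenvalue-ordered
    eigenvalues: np.ndarray  # (D,) descending, >= 0
    scaled: bool = False
    scales: np.ndarray | None = None  # per-column std when scaled

    @property
    def n_dims(self) -> int:
        return len(self.means)

    def to_json(self, path: str | os.PathLike) -> None:
        doc = {
            "means": self.means.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "scaled": self.scaled,
            "scales": None if self.scales is None else self.scales.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PCAModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            means=np.asarray(doc["means"], dtype=float),
            loadings=np.asarray(doc["loadings"], dtype=float),
            eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
            scaled=bool(doc.get("scaled", False)),
            scales=None if doc.get("scales") is None else np.asarray(doc["scales"], dtype=float),
        )


def fit_pca(X: np.ndarray, scale: bool = False) -> PCAModel:
    """Fit PCA by eigendecomposition of the covariance matrix.

    Sign convention: each loading column is flipped so that its
    largest-magnitude entry is positive, making the model deterministic.
    Degenerate (constant) data yields zero eigenvalues, not an error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2D matrix")
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit a PCA")
    means = X.mean(axis=0)
    Xc = X - means
    scales = None
    if scale:
        scales = Xc.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        Xc = Xc / scales
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude entry of each column positive
    for c in range(d):
        col = eigvecs[:, c]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            eigvecs[:, c] = -col
    return PCAModel(means=means, loadings=eigvecs, eigenvalues=eigvals,
                    scaled=scale, scales=scales)


def project(model: PCAModel, X: np.ndarray, k: int = 3) -> np.ndarray:
    """Project rows of X onto the first k principal components."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_dims:
        raise ValueError(
            f"dimension mismatch: model has {model.n_dims} dims, X has {X.shape[1]}"
        )
    if not 1 <= k <= model.n_dims:
        raise ValueError(f"k must be in 1..{model.n_dims}, got {k}")
    Xc = X - model.means
    if model.scaled:
        Xc = Xc / model.scales
    return Xc @ model.loadings[:, :k]


def variance_coverage(model: PCAModel, k: int) -> float:
    """Fraction of total data variance covered by the first k components."""
    if not 1 <= k <= model.n_dims:
        raise ValueError(f"k must be in 1..{model.n_dims}, got {k}")
    total = model.eigenvalues.sum()
    if total == 0:
        return 1.0
    return float(model.eigenvalues[:k].sum() / total)


def _decode_pair_indices(t: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices of the upper triangle (pdist order) to (i, j)."""
    t = t.astype(np.int64)
    # i is the largest integer with i*(2n-i-1)/2 <= t
    i = ((2 * n - 1) - np.sqrt((2 * n - 1) ** 2 - 8 * t.astype(float))) // 2
    i = i.astype(np.int64)
    # guard against float rounding at block boundaries
    offset = i * (2 * n - i - 1) // 2
    over = offset > t
    while np.any(over):
        i[over] -= 1
        offset = i * (2 * n - i - 1) // 2
        over = offset > t
    under = (i + 1) * (2 * n - i - 2) // 2 <= t
    while np.any(under):
        i[under] += 1
        offset = i * (2 * n - i - 1) // 2
        under = (i + 1) * (2 * n - i - 2) // 2 <= t
    j = t - offset + i + 1
    return i, j


def distance_correlation(
    coords: np.ndarray,
    fps: np.ndarray,
    n_pairs: int = 1_000_000,
    seed: int = 0,
    metric: str = "euclidean",
) -> float:
    """Pearson correlation between pairwise distances in the projected
    subspace and in the original fingerprint space.

    Pairs are sampled uniformly without replacement (all pairs when the
    total count fits within ``n_pairs``). ``metric`` selects the
    distance used in the original space ('euclidean' or 'cityblock');
    the subspace always uses Euclidean distance.
    """
    coords = np.asarray(coords, dtype=float)
    fps = np.asarray(fps, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = len(coords)
    if len(fps) != n:
        raise ValueError("coords and fps must have the same number of rows")
    if n < 3:
        raise ValueError("need at least 3 molecules")
    if metric not in ("euclidean", "cityblock"):
        raise ValueError(f"unknown metric {metric!r}")

    total = n * (n - 1) // 2
    if total <= n_pairs:
        d_low = pdist(coords, metric="euclidean")
        d_high = pdist(fps, metric=metric)
    else:
        rng = np.random.default_rng(seed)
        t = rng.choice(total, size=n_pairs, replace=False)
        i, j = _decode_pair_indices(t, n)
        diff = coords[i] - coords[j]
        d_low = np.sqrt((diff**2).sum(axis=1))
        fdiff = fps[i] - fps[j]
        if metric == "euclidean":
            d_high = np.sqrt((fdiff**2).sum(axis=1))
        else:
            d_high = np.abs(fdiff).sum(axis=1)

    if d_low.std() == 0 or d_high.std() == 0:
        raise ZeroVarianceError("distance sets have zero variance; correlation undefined")
    return float(np.corrcoef(d_low, d_high)[0, 1])
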