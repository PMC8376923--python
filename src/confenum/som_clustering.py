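"""Conformer-set reduction with a periodic self-organizing map.

Each conformation is encoded from its CA-CA distance matrix: the rows of
the distance matrix are treated as observations, their covariance

    C[i, j] = (1/n) * sum_k (d[i, k] - dbar_i) * (d[j, k] - dbar_j)

is diagonalized, and the four largest eigenvalues with their eigenvectors
form an input vector of length 4(n+1).  The encoding depends on internal
distances only, so it is invariant under rigid-body motion (and blind to
chirality, by construction).

A toroidal 2D Kohonen map is trained on the encoded vectors; the U-matrix
(mean Euclidean distance of each neuron to its eight toroidal neighbors)
is computed, and for every occupied local minimum of the U-matrix the
first conformation assigned to that neuron becomes the representative of
its basin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_core import Conformation

__all__ = [
    "EncodedConformation",
    "SOMSettings",
    "SOMGrid",
    "encode",
    "train_som",
    "umatrix",
    "bmu_assignments",
    "extract_representatives",
    "maybe_cluster",
]

N_EIGENPAIRS = 4


class EncodingError(ValueError):
    pass


@dataclass
class EncodedConformation:
    """Four largest covariance eigenvalues + eigenvectors, length 4(n+1)."""

    vector: np.ndarray
    n_ca: int


@dataclass(frozen=True)
class SOMSettings:
    rows: int = 100
    cols: int = 100
    periodic: bool = True
    epochs: int = 2
    lr_start: float = 0.5
    lr_end: float = 0.05
    radius_start: float | None = None   # default max(rows, cols)/2
    radius_end: float = 1.0


@dataclass
class SOMGrid:
    settings: SOMSettings
    weights: np.ndarray          # (rows, cols, dim)
    seed: int = 0

    @property
    def rows(self) -> int:
        return self.weights.shape[0]

    @property
    def cols(self) -> int:
        return self.weights.shape[1]


def encode(conf: Conformation) -> EncodedConformation:
    """Distance-covariance encoding of one conformation."""
    ca = conf.ca_coords()
    n = ca.shape[0]
    if n < 5:
        raise EncodingError("fragment too small to encode (need >= 5 CA atoms)")
    diff = ca[:, None, :] - ca[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=2))
    dc = d - d.mean(axis=1, keepdims=True)
    cov = dc @ dc.T / n
    evals, evecs = np.linalg.eigh(cov)       # ascending
    order = np.argsort(evals)[::-1][:N_EIGENPAIRS]
    lams = evals[order]
    vecs = evecs[:, order]
    # fix eigenvector sign: largest-magnitude component positive
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    vector = np.concatenate([lams, vecs.T.ravel()])
    return EncodedConformation(vector, n)


def _stack(vectors) -> np.ndarray:
    arrs = [
        v.vector if isinstance(v, EncodedConformation) else np.asarray(v, dtype=float)
        for v in vectors
    ]
    lengths = {a.shape[0] for a in arrs}
    if len(lengths) != 1:
        raise EncodingError("encoding mismatch: input vectors differ in length")
    return np.stack(arrs)


def _toroidal_sq_dist(rows, cols):
    """Squared toroidal grid distance from every cell to cell (0, 0)."""
    dr = np.minimum(np.arange(rows), rows - np.arange(rows))
    dc = np.minimum(np.arange(cols), cols - np.arange(cols))
    return dr[:, None] ** 2 + dc[None, :] ** 2


def train_som(vectors, settings: SOMSettings | None = None, seed: int = 0) -> SOMGrid:
    """Train a periodic Kohonen map on the encoded vectors.

    Neurons are initialized uniformly over the per-coordinate range of the
    inputs.  One step presents one input: the best-matching unit and its
    Gaussian neighborhood (toroidal) move toward the input; learning rate
    decays linearly, neighborhood radius exponentially.  Deterministic for
    a given seed.
    """
    settings = settings or SOMSettings()
    data = _stack(vectors)
    if data.shape[0] < 1:
        raise EncodingError("need at least one input vector")
    rng = np.random.default_rng(seed)
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    rows, cols = settings.rows, settings.cols
    weights = rng.uniform(lo, hi, size=(rows, cols, data.shape[1]))

    radius0 = settings.radius_start or max(rows, cols) / 2.0
    n_steps = settings.epochs * data.shape[0]
    base_sq = _toroidal_sq_dist(rows, cols)
    step = 0
    for _epoch in range(settings.epochs):
        order = rng.permutation(data.shape[0])
        for idx in order:
            frac = step / max(1, n_steps - 1)
            lr = settings.lr_start + (settings.lr_end - settings.lr_start) * frac
            radius = radius0 * (settings.radius_end / radius0) ** frac
            x = data[idx]
            delta = weights - x
            sq = (delta * delta).sum(axis=2)
            r, c = np.unravel_index(np.argmin(sq), sq.shape)
            h = lr * np.exp(
                -np.roll(np.roll(base_sq, r, axis=0), c, axis=1)
                / (2.0 * radius * radius)
            )
            weights -= h[:, :, None] * delta
            step += 1
    return SOMGrid(settings, weights, seed)


def umatrix(som: SOMGrid) -> np.ndarray:
    """Mean Euclidean distance of each neuron to its 8 toroidal neighbors."""
    w = som.weights
    out = np.zeros(w.shape[:2])
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(w, -dr, axis=0), -dc, axis=1)
            out += np.sqrt(((w - shifted) ** 2).sum(axis=2))
    return out / 8.0


def bmu_assignments(som: SOMGrid, vectors) -> list:
    """Best-matching (row, col) for each input vector, in input order."""
    data = _stack(vectors)
    flat = som.weights.reshape(-1, som.weights.shape[2])
    out = []
    for x in data:
        sq = ((flat - x) ** 2).sum(axis=1)
        k = int(np.argmin(sq))
        out.append((k // som.cols, k % som.cols))
    return out


def _local_minima(um: np.ndarray):
    """Toroidal 8-neighborhood local minima: <= all neighbors, < at least one."""
    rows, cols = um.shape
    le_all = np.ones_like(um, dtype=bool)
    lt_any = np.zeros_like(um, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = np.roll(np.roll(um, -dr, axis=0), -dc, axis=1)
            le_all &= um <= nb
            lt_any |= um < nb
    return {(r, c) for r, c in zip(*np.nonzero(le_all & lt_any))}


def extract_representatives(som: SOMGrid, um: np.ndarray, assignments, conformations):
    """First conformation stored in each occupied U-matrix local minimum.

    Falls back to the global U-matrix minimum among occupied neurons when
    no occupied local minimum exists.
    """
    first_in = {}
    for conf, cell in zip(conformations, assignments):
        first_in.setdefault(tuple(cell), conf)
    minima = _local_minima(um)
    occupied_minima = [cell for cell in sorted(first_in) if cell in minima]
    if not occupied_minima:
        occupied = sorted(first_in)
        best = min(occupied, key=lambda cell: um[cell])
        return [first_in[best]]
    return [first_in[cell] for cell in occupied_minima]


def maybe_cluster(
    conformations,
    threshold: int = 1000,
    settings: SOMSettings | None = None,
    seed: int = 0,
):
    """Reduce the set via SOM representatives when it exceeds the threshold.

    Sets of ``threshold`` or fewer conformations are returned unchanged
    (the reduction triggers only when the count is strictly larger).
    """
    if len(conformations) <= threshold:
        return list(conformations)
    encoded = [encode(c) for c in conformations]
    som = train_som(encoded, settings, seed)
    um = umatrix(som)
    assignments = bmu_assignments(som, encoded)
    return extract_representatives(som, um, assignments, conformations)
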