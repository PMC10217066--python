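"""Kohonen Self-Organizing Map: competition, cooperation, adaptation.

A rectangular lattice of units, each carrying a weight vector in input
space.  Training presents records in a seeded shuffled order; each
presentation finds the best matching unit (BMU, nearest weight vector in
Euclidean distance) and moves every unit toward the record in proportion
to a Gaussian neighborhood kernel on the lattice.  Learning rate and
neighborhood radius decay exponentially between their initial and final
values over the epochs.  Clusters are identified with map units — a 2×3
grid yields six clusters — with no secondary agglomeration.

Map quality is summarized by the quantization error (mean distance of a
record to its BMU) and the topographic error (fraction of records whose
two best units are not lattice-adjacent, 8-neighborhood).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SOMGrid",
    "ClusterAssignment",
    "MapQuality",
    "init_grid",
    "find_bmu",
    "neighborhood_weight",
    "train",
    "assign_clusters",
    "map_quality",
    "select_grid_size",
]


@dataclass(frozen=True)
class SOMGrid:
    """Lattice of unit weight vectors plus learning and radius schedules.

    Unit ``u`` sits at lattice coordinate ``(u // cols, u % cols)``; its
    weight vector is ``weights[u]``.
    """

    rows: int
    cols: int
    weights: np.ndarray  # (rows * cols, dim)
    lr_initial: float = 0.5
    lr_final: float = 0.01
    radius_initial: float | None = None
    radius_final: float = 0.3
    epochs_trained: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        weights = np.asarray(self.weights, dtype=float)
        if weights.shape[0] != self.rows * self.cols or weights.ndim != 2:
            raise ValueError("weights must be (rows*cols, dim)")
        if not np.isfinite(weights).all():
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", weights)
        radius = self.radius_initial
        if radius is None:
            radius = max(self.rows, self.cols) / 2.0
        if radius <= 0 or self.radius_final <= 0:
            raise ValueError("radii must be positive")
        object.__setattr__(self, "radius_initial", float(radius))

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    @property
    def lattice_coords(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_units), self.cols)
        return np.column_stack([r, c]).astype(float)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "weights": self.weights.tolist(),
            "lr_initial": self.lr_initial,
            "lr_final": self.lr_final,
            "radius_initial": self.radius_initial,
            "radius_final": self.radius_final,
            "epochs_trained": self.epochs_trained,
            "seed": self.seed,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SOMGrid":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        payload["weights"] = np.asarray(payload["weights"], dtype=float)
        return cls(**payload)


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-record BMU index (0-based) and per-unit member counts."""

    unit_index: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.unit_index.shape[0]:
            raise ValueError("counts must sum to the number of records")


@dataclass(frozen=True)
class MapQuality:
    quantization_error: float
    topographic_error: float


def init_grid(
    rows: int, cols: int, dim: int, X: np.ndarray, seed: int
) -> SOMGrid:
    """Random initialization: weights uniform within each input dimension's range."""
    if dim < 1:
        raise ValueError("dim must be positive")
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("X must be non-empty")
    if X.ndim != 2 or X.shape[1] != dim:
        raise ValueError("X must be 2-D with `dim` columns")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    rng = np.random.default_rng(seed)
    weights = rng.uniform(lo, hi, size=(rows * cols, dim))
    return SOMGrid(rows=rows, cols=cols, weights=weights, seed=seed)


def find_bmu(grid: SOMGrid, x: np.ndarray) -> int:
    """Index of the unit nearest to ``x``; ties go to the lowest index."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("query vector must be finite")
    if x.shape != (grid.dim,):
        raise ValueError(f"expected a vector of length {grid.dim}")
    d2 = ((grid.weights - x[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def neighborhood_weight(
    grid: SOMGrid, bmu: int, unit: int, radius: float
) -> float:
    """Gaussian cooperation kernel exp(−g²/(2r²)) on lattice coordinates."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = grid.lattice_coords
    g2 = float(((coords[bmu] - coords[unit]) ** 2).sum())
    return float(np.exp(-g2 / (2.0 * radius**2)))


def _schedule(initial: float, final: float, t: int, total: int) -> float:
    """Exponential decay from initial (t=0) to final (t=total−1)."""
    if initial == final or total <= 1:
        return final
    return initial * (final / initial) ** (t / (total - 1))


def train(grid: SOMGrid, X: np.ndarray, epochs: int = 200) -> SOMGrid:
    """Online SOM training; returns a new grid, input grid untouched.

    Presentation order is reshuffled every epoch from a stream seeded by
    (grid seed, epochs already trained), so repeated calls continue
    deterministically rather than replaying the same order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != grid.dim:
        raise ValueError("X must be 2-D with grid.dim columns")
    if epochs == 0:
        return grid
    if epochs < 0:
        raise ValueError("epochs must be nonnegative")
    rng = np.random.default_rng([grid.seed, grid.epochs_trained, 0x50D])
    weights = grid.weights.copy()
    coords = grid.lattice_coords
    lattice_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    for epoch in range(epochs):
        lr = _schedule(grid.lr_initial, grid.lr_final, epoch, epochs)
        radius = _schedule(grid.radius_initial, grid.radius_final, epoch, epochs)
        h_all = np.exp(-lattice_d2 / (2.0 * radius**2))
        order = rng.permutation(X.shape[0])
        for i in order:
            x = X[i]
            d2 = ((weights - x[None, :]) ** 2).sum(axis=1)
            bmu = int(np.argmin(d2))
            h = h_all[bmu]
            weights += lr * h[:, None] * (x[None, :] - weights)
    return replace(
        grid, weights=weights, epochs_trained=grid.epochs_trained + epochs
    )


def assign_clusters(grid: SOMGrid, X: np.ndarray) -> ClusterAssignment:
    """Map every record to its BMU and tally per-unit member counts."""
    X = np.asarray(X, dtype=float)
    d2 = ((X[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=-1)
    units = np.argmin(d2, axis=1)
    counts = np.bincount(units, minlength=grid.n_units)
    return ClusterAssignment(unit_index=units, counts=counts)


def map_quality(grid: SOMGrid, X: np.ndarray) -> MapQuality:
    """Quantization error and topographic error of the map on ``X``."""
    X = np.asarray(X, dtype=float)
    d2 = ((X[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=-1)
    best = np.argmin(d2, axis=1)
    qe = float(np.sqrt(d2[np.arange(X.shape[0]), best]).mean())
    if grid.n_units == 1:
        return MapQuality(quantization_error=qe, topographic_error=0.0)
    d2_masked = d2.copy()
    d2_masked[np.arange(X.shape[0]), best] = np.inf
    second = np.argmin(d2_masked, axis=1)
    coords = grid.lattice_coords
    delta = np.abs(coords[best] - coords[second])
    adjacent = np.maximum(delta[:, 0], delta[:, 1]) <= 1
    te = float(1.0 - adjacent.mean())
    return MapQuality(quantization_error=qe, topographic_error=te)


def select_grid_size(
    candidates: Sequence[tuple[int, int]],
    X: np.ndarray,
    seed: int,
    epochs: int = 200,
) -> tuple[tuple[int, int], dict[tuple[int, int], MapQuality]]:
    """Train each candidate grid and pick the best map quality.

    Quality is ranked by quantization error with topographic error as the
    tie-break (both lower = better).
    """
    X = np.asarray(X, dtype=float)
    results: dict[tuple[int, int], MapQuality] = {}
    for rows, cols in candidates:
        grid = train(init_grid(rows, cols, X.shape[1], X, seed), X, epochs)
        results[(rows, cols)] = map_quality(grid, X)
    best = min(
        results,
        key=lambda rc: (
            results[rc].quantization_error,
            results[rc].topographic_error,
        ),
    )
    return best, results
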