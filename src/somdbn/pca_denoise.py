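"""Principal-component projection used to denoise inputs to the SOM.

Components are the eigenvectors of the covariance of the centred data,
computed through the thin SVD for numerical stability.  ``k`` may be a
component count or a variance fraction (smallest count reaching it).
Scores feed the SOM and the cluster-visualization exports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PCAModel", "fit_pca", "transform", "inverse_transform", "scores_to_csv"]


@dataclass(frozen=True)
class PCAModel:
    """Orthonormal loadings (k × n), explained variances, and column centres."""

    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]


def fit_pca(X: np.ndarray, k: int | float) -> PCAModel:
    """Fit a PCA with ``k`` components (int) or enough to explain ``k`` variance.

    Raises on missing cells (impute or mean-fill first), on ``k`` exceeding
    the number of columns, and on all-constant input (no variance to split).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("X contains missing cells; fill them before PCA")
    m, n = X.shape
    mean = X.mean(axis=0)
    centered = X - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (m - 1)
    total = eigvals.sum()
    if total == 0:
        raise ValueError("X is constant; PCA undefined")
    ratio = eigvals / total
    if isinstance(k, float) and 0 < k < 1:  # variance fraction
        n_comp = int(np.searchsorted(np.cumsum(ratio), k - 1e-12) + 1)
    else:
        n_comp = int(k)
        if not 1 <= n_comp <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
    # sign convention: largest-|.| loading entry positive, for reproducibility
    comps = vt[:n_comp].copy()
    for i in range(n_comp):
        idx = int(np.argmax(np.abs(comps[i])))
        if comps[i, idx] < 0:
            comps[i] = -comps[i]
    return PCAModel(
        components=comps,
        explained_variance=eigvals[:n_comp],
        explained_variance_ratio=ratio[:n_comp],
        mean=mean,
    )


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project (column-centred) records onto the loadings."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"expected {model.mean.shape[0]} columns, got {X.shape[1]}"
        )
    return (X - model.mean[None, :]) @ model.components.T


def inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map scores back to the (centred-then-unshifted) feature space."""
    scores = np.asarray(scores, dtype=float)
    return scores @ model.components + model.mean[None, :]


def scores_to_csv(model: PCAModel, X: np.ndarray, path: str | Path) -> None:
    """Export component scores for external cluster-visualization plots."""
    scores = transform(model, X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    pd.DataFrame(scores, columns=cols).to_csv(path, index=False)
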