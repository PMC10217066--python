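"""Missing-value prediction by truncated-SVD matrix completion.

The procedure: z-score each column using its observed cells (B̄_j, σ_j),
set missing z-scores to 0 (i.e. start them at the column mean), take the
best rank-d approximation Z_d of the z-score matrix, and predict each
missing cell as B̄_j + σ_j · (Z_d)_ij.  A single pass cannot use any
structure at the missing cells themselves, so :func:`impute` iterates the
cycle — refill the missing cells with their current predictions and
re-approximate — to a fixed point.  Observed cells are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationParams",
    "NormalizedMatrix",
    "RankDApproximation",
    "normalize",
    "rank_d_approximation",
    "predict_missing",
    "impute",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column observed-cell mean B̄_j and sample SD σ_j."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D of equal length")
        if (self.sd < 0).any():
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class NormalizedMatrix:
    """Z-score matrix plus the parameters and source matrix it came from."""

    Z: np.ndarray
    params: NormalizationParams
    source: np.ndarray


@dataclass(frozen=True)
class RankDApproximation:
    """Best rank-d least-squares approximation with its truncated factors."""

    Z_d: np.ndarray
    d: int
    u: np.ndarray
    s: np.ndarray
    vt: np.ndarray


def normalize(B: np.ndarray, mask: np.ndarray | None = None) -> NormalizedMatrix:
    """Column-wise z-scoring over observed cells; missing z-scores are 0.

    B̄_j and σ_j (sample SD, divisor m_obs − 1) are computed from observed
    cells only.  A constant observed column has σ_j = 0; it is replaced by
    1 (with a logged warning) so its z-scores are 0.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2:
        raise ValueError("B must be 2-D")
    m, n = B.shape
    if mask is None:
        mask = np.zeros(B.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != B.shape:
        raise ValueError("mask shape must match B")
    observed = ~mask
    n_obs = observed.sum(axis=0)
    if (n_obs < 2).any():
        bad = int(np.argmin(n_obs))
        raise ValueError(
            f"column {bad} has {n_obs[bad]} observed cells; need at least 2"
        )
    mean = np.empty(n)
    sd = np.empty(n)
    for j in range(n):
        col = B[observed[:, j], j]
        mean[j] = col.mean()
        sd[j] = col.std(ddof=1)
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning(
            "constant observed column(s) %s: sd set to 1",
            np.flatnonzero(zero_sd).tolist(),
        )
        sd = np.where(zero_sd, 1.0, sd)
    Z = (B - mean[None, :]) / sd[None, :]
    Z[mask] = 0.0
    return NormalizedMatrix(Z=Z, params=NormalizationParams(mean, sd), source=B)


def _deterministic_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip singular-vector pairs so each u column's largest-|.| entry is positive."""
    u = u.copy()
    vt = vt.copy()
    for k in range(u.shape[1]):
        idx = int(np.argmax(np.abs(u[:, k])))
        if u[idx, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    return u, vt


def rank_d_approximation(Z: np.ndarray, d: int) -> RankDApproximation:
    """Best rank-d approximation via the truncated singular value expansion."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("Z must be 2-D")
    if not 1 <= d <= min(Z.shape):
        raise ValueError(f"d must be in [1, {min(Z.shape)}], got {d}")
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    u, vt = _deterministic_signs(u[:, :d], vt[:d, :])
    s = s[:d]
    Z_d = (u * s[None, :]) @ vt
    return RankDApproximation(Z_d=Z_d, d=d, u=u, s=s, vt=vt)


def predict_missing(
    approx: RankDApproximation,
    params: NormalizationParams,
    mask: np.ndarray,
    B: np.ndarray,
) -> np.ndarray:
    """Fill masked cells with B̄_j + σ_j (Z_d)_ij; observed cells unchanged."""
    B = np.asarray(B, dtype=float)
    if approx.Z_d.shape != B.shape or mask.shape != B.shape:
        raise ValueError("shape mismatch between approximation, mask and B")
    filled = B.copy()
    pred = params.mean[None, :] + params.sd[None, :] * approx.Z_d
    filled[mask] = pred[mask]
    return filled


def impute(
    B: np.ndarray,
    mask: np.ndarray,
    d: int = 2,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, list[dict]]:
    """Iterated normalize → rank-d approximate → predict cycle.

    Missing cells start at their column means (z-score 0) and are refilled
    with each cycle's predictions until the maximum absolute change at a
    missing cell (on the original scale) drops below ``tol`` or
    ``max_iter`` is reached.  B̄_j and σ_j average over the full dense
    column, so they are recomputed from the refilled matrix each cycle;
    observed cells are reset to their original values every time and are
    never altered in the output.  Returns the filled matrix and a
    per-iteration log; non-convergence is flagged in the final log entry.
    """
    B = np.asarray(B, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != B.shape:
        raise ValueError("mask shape must match B")
    # start at the observed-cell column means (z-score 0 under `normalize`)
    filled = predict_missing_mean_fill(B, mask)
    if not mask.any():
        return filled, [
            {"iteration": 1, "max_change": 0.0, "converged": True, "note": "no missing cells"}
        ]
    log: list[dict] = []
    converged = False
    for iteration in range(1, max_iter + 1):
        norm = normalize(filled)  # dense matrix: full-column B̄_j, σ_j
        approx = rank_d_approximation(norm.Z, d)
        new = predict_missing(approx, norm.params, mask, B)
        max_change = float(np.max(np.abs(new[mask] - filled[mask])))
        filled = new
        log.append(
            {"iteration": iteration, "max_change": max_change, "converged": False}
        )
        if max_change < tol:
            converged = True
            log[-1]["converged"] = True
            break
    if not converged:
        log[-1]["flag"] = "max_iter reached without convergence"
        logger.warning("impute: no convergence after %d iterations", max_iter)
    return filled, log


def predict_missing_mean_fill(B: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked cells replaced by their column's observed-cell mean."""
    params = normalize(B, mask).params
    filled = np.asarray(B, dtype=float).copy()
    filled[np.asarray(mask, dtype=bool)] = np.broadcast_to(
        params.mean[None, :], B.shape
    )[mask]
    return filled
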