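"""Backward stepwise discriminant feature selection (Wilks' lambda).

Wilks' lambda on a feature subset is det(W)/det(T), where W and T are the
within-group and total cross-product (scatter) matrices.  Small lambda
means strong group separation.  The partial F statistic for removing one
feature from a subset compares the lambda with and without it:

    F = (n − g − p) / (g − 1) · (Λ_without / Λ_with − 1)

with g groups (two here) and p features retained after the removal;
under the null it follows F(g − 1, n − g − p).  Backward selection starts
from all features and repeatedly drops the feature with the largest
p-value among those exceeding the stay level ``alpha``, stopping when all
survivors are significant or one feature remains.  With a single feature,
1/Λ − 1 = t²/(n − 2) for the pooled two-sample t statistic, which serves
as an exact cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StepdiscStep",
    "StepdiscResult",
    "wilks_lambda",
    "partial_f_to_remove",
    "backward_select",
]


@dataclass(frozen=True)
class StepdiscStep:
    feature_removed: int
    partial_f: float
    p_value: float
    wilks_after: float


@dataclass(frozen=True)
class StepdiscResult:
    """Selected subset plus the per-step removal trace."""

    selected: tuple[int, ...]
    steps: tuple[StepdiscStep, ...]
    alpha: float

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.steps) + 1),
                "feature_removed": [s.feature_removed for s in self.steps],
                "partial_F": [s.partial_f for s in self.steps],
                "p_value": [s.p_value for s in self.steps],
                "wilks_lambda_after": [s.wilks_after for s in self.steps],
            }
        )

    def trace_to_csv(self, path: str | Path) -> None:
        self.trace_frame().to_csv(path, index=False)


def _scatter(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    total_centered = X - X.mean(axis=0)
    T = total_centered.T @ total_centered
    W = np.zeros_like(T)
    for cls in np.unique(y):
        group = X[y == cls]
        centered = group - group.mean(axis=0)
        W += centered.T @ centered
    return W, T


def _validate(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be 2-D with one label per record")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 records")
    return X, y


def wilks_lambda(
    X: np.ndarray, y: np.ndarray, subset: Sequence[int]
) -> float:
    """Λ = det(W)/det(T) on the given feature subset."""
    X, y = _validate(X, y)
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    W, T = _scatter(X[:, subset], y)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or not np.isfinite(logdet_w):
        raise ValueError(
            f"singular within-group scatter on subset {tuple(subset)}"
        )
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise ValueError(f"singular total scatter on subset {tuple(subset)}")
    lam = float(np.exp(logdet_w - logdet_t))
    return min(lam, 1.0)


def partial_f_to_remove(
    X: np.ndarray,
    y: np.ndarray,
    subset: Sequence[int],
    feature: int,
) -> tuple[float, float]:
    """Partial F (and p-value) for dropping ``feature`` from ``subset``.

    With the feature removed, p = |subset| − 1 variables remain; removing
    the only feature compares against the empty model (Λ_without = 1), in
    which case F reduces to the squared pooled two-sample t statistic.
    """
    subset = list(subset)
    if feature not in subset:
        raise ValueError(f"feature {feature} not in subset")
    if np.asarray(X)[:, feature].std() == 0:
        return 0.0, 1.0  # a constant feature cannot discriminate
    lam_with = wilks_lambda(X, y, subset)
    remaining = [f for f in subset if f != feature]
    lam_without = wilks_lambda(X, y, remaining) if remaining else 1.0
    n = np.asarray(X).shape[0]
    g = 2
    p = len(remaining)
    df2 = n - g - p
    if df2 < 1:
        raise ValueError("not enough records for the partial F test")
    ratio = max(lam_without / lam_with - 1.0, 0.0)
    f_stat = df2 / (g - 1) * ratio
    p_value = float(stats.f.sf(f_stat, g - 1, df2))
    return float(f_stat), p_value


def backward_select(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.15
) -> StepdiscResult:
    """Backward elimination with the partial-F stay rule.

    Repeatedly removes the feature with the largest p-value among those
    with p > ``alpha`` (ties to the lowest feature index), until every
    remaining feature is significant or only one is left.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    X, y = _validate(X, y)
    subset = list(range(X.shape[1]))
    steps: list[StepdiscStep] = []
    prev_lambda = wilks_lambda(X, y, subset)
    while len(subset) > 1:
        stats_per_feature = [
            partial_f_to_remove(X, y, subset, f) for f in subset
        ]
        p_values = np.array([p for _, p in stats_per_feature])
        removable = p_values > alpha
        if not removable.any():
            break
        # largest p first; np.argmax returns the first (lowest-index) maximum
        k = int(np.argmax(np.where(removable, p_values, -np.inf)))
        feature = subset[k]
        f_stat, p_value = stats_per_feature[k]
        subset.remove(feature)
        lam_after = wilks_lambda(X, y, subset)
        if lam_after < prev_lambda - 1e-10:
            raise AssertionError(
                "Wilks' lambda decreased after a removal — numerical fault"
            )
        prev_lambda = lam_after
        steps.append(
            StepdiscStep(
                feature_removed=feature,
                partial_f=f_stat,
                p_value=p_value,
                wilks_after=lam_after,
            )
        )
    return StepdiscResult(
        selected=tuple(subset), steps=tuple(steps), alpha=alpha
    )
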