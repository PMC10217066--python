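"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators:

* :func:`generate_low_rank` — a planted low-rank matrix with MCAR masking,
  for exercising SVD matrix completion against known truth.
* :func:`generate_clustered_classes` — Gaussian cluster centres with
  approximately low-rank within-cluster covariance, a binary outcome driven
  by a logistic link on a planted informative-feature subset (the link
  direction alternates across clusters, so clustering genuinely carries
  information), and column-specific MCAR missingness.
* :func:`generate_pima_like_cohort` — a synthetic stand-in for the public
  Pima-Indians-Diabetes screening cohort: 768 records, 500 controls and 268
  diabetic patients, per-column zero-sentinel counts and published marginal
  moments planted exactly.  It emulates the published cohort description,
  not the joint distribution of the real measurements.

Missingness is MCAR throughout: the mask is drawn independently of all
values, which is the regime in which mean-anchored SVD imputation is
unbiased.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .data_io import PIMA_FEATURES, FeatureTable

__all__ = [
    "SyntheticTruth",
    "generate_low_rank",
    "generate_clustered_classes",
    "generate_pima_like_cohort",
    "PIMA_ZERO_COUNTS",
    "PIMA_MOMENTS",
]

#: Published zero-sentinel counts of the screening cohort (out of 768).
PIMA_ZERO_COUNTS: dict[str, int] = {
    "glucose": 5,
    "blood_pressure": 35,
    "skin_thickness": 227,
    "insulin": 374,
    "bmi": 27,
}

#: Published per-column mean and SD of the screening cohort.
PIMA_MOMENTS: dict[str, tuple[float, float]] = {
    "pregnancies": (3.84, 3.36),
    "glucose": (121.67, 30.46),
    "blood_pressure": (72.38, 12.10),
    "skin_thickness": (29.08, 8.89),
    "insulin": (141.76, 89.10),
    "bmi": (32.43, 6.88),
    "pedigree": (0.47, 0.33),
    "age": (33.24, 11.76),
}

PIMA_N_RECORDS = 768
PIMA_N_CASES = 268


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a synthetic fixture.

    ``true_values`` carries the pre-masking value at every masked cell and
    NaN elsewhere; ``true_cluster_id`` is 1-based.
    """

    true_values: np.ndarray
    true_cluster_id: np.ndarray
    true_informative_features: tuple[str, ...]
    seed: int
    params: dict = field(default_factory=dict)

    def masked_rmse(self, filled: np.ndarray, mask: np.ndarray) -> float:
        """RMSE between an imputed matrix and the planted truth at masked cells."""
        diff = filled[mask] - self.true_values[mask]
        return float(np.sqrt(np.mean(diff**2)))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "true_cluster_id": self.true_cluster_id.tolist(),
            "true_informative_features": list(self.true_informative_features),
            "true_values": [
                [None if np.isnan(v) else v for v in row]
                for row in self.true_values
            ],
        }
        Path(path).write_text(json.dumps(payload))


def _mcar_mask(
    m: int, n: int, mask_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    n_masked = int(round(mask_fraction * m * n))
    flat = rng.choice(m * n, size=n_masked, replace=False)
    mask = np.zeros(m * n, dtype=bool)
    mask[flat] = True
    return mask.reshape(m, n)


def generate_low_rank(
    m: int,
    n: int,
    rank: int,
    noise_sd: float,
    mask_fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Planted low-rank matrix ``B = L @ R + noise`` with an MCAR mask.

    ``L`` is m-by-rank and ``R`` rank-by-n, both with i.i.d. standard
    normal entries.  The returned matrix is fully populated; the mask says
    which cells an imputer should treat as missing.  Raises if the mask
    leaves any column with fewer than two observed cells.
    """
    if not 1 <= rank <= min(m, n):
        raise ValueError("rank must be in [1, min(m, n)]")
    if not 0 <= mask_fraction < 1:
        raise ValueError("mask_fraction must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    left = rng.standard_normal((m, rank))
    right = rng.standard_normal((rank, n))
    matrix = left @ right
    if noise_sd > 0:
        matrix = matrix + rng.normal(0.0, noise_sd, size=(m, n))
    mask = _mcar_mask(m, n, mask_fraction, rng)
    observed_per_col = (~mask).sum(axis=0)
    if (observed_per_col < 2).any():
        bad = int(np.argmin(observed_per_col))
        raise ValueError(
            f"mask leaves column {bad} with {observed_per_col[bad]} observed cells"
        )
    true_values = np.full((m, n), np.nan)
    true_values[mask] = matrix[mask]
    truth = SyntheticTruth(
        true_values=true_values,
        true_cluster_id=np.ones(m, dtype=int),
        true_informative_features=(),
        seed=seed,
        params={
            "m": m,
            "n": n,
            "rank": rank,
            "noise_sd": noise_sd,
            "mask_fraction": mask_fraction,
        },
    )
    return matrix, mask, truth


def _feature_names(n: int) -> tuple[str, ...]:
    if n == len(PIMA_FEATURES):
        return PIMA_FEATURES
    return tuple(f"f{j + 1}" for j in range(n))


def generate_clustered_classes(
    m: int,
    n: int = 8,
    n_clusters: int = 6,
    separation: float = 10.0,
    class_balance: float = PIMA_N_CASES / PIMA_N_RECORDS,
    missing_rates: Mapping[str, float] | Sequence[float] | None = None,
    seed: int = 0,
    n_informative: int = 3,
    noise_sd: float = 0.3,
    factor_sd: float = 2.0,
    within_rank: int = 2,
    label_sharpness: float = 25.0,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Planted-cluster, planted-signal binary classification fixture.

    Cluster centres are isotropic Gaussian draws rescaled so the minimum
    pairwise distance equals ``separation``.  Within a cluster, records are
    centre + rank-``within_rank`` factor structure (scale ``factor_sd``) +
    isotropic noise, so each cluster's submatrix is approximately low rank
    — the regime the SVD imputer targets.  The class posterior is a steep
    logistic in a score on ``n_informative`` designated features; the score
    direction flips sign between even- and odd-numbered clusters, so a
    single global decision rule cannot match per-cluster rules.  The
    intercept is set so the marginal positive rate is ``class_balance``.
    Masked cells have their value replaced by the 0 sentinel and the mask
    bit set; the truth records the pre-masking values.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if not 0 <= class_balance <= 1:
        raise ValueError("class_balance must be in [0, 1]")
    if n_informative > n:
        raise ValueError("more informative features than features")
    rng = np.random.default_rng(seed)
    names = _feature_names(n)

    centers = rng.standard_normal((n_clusters, n))
    if n_clusters > 1:
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        min_dist = dist[np.triu_indices(n_clusters, k=1)].min()
        if min_dist <= 0:
            raise ValueError(
                f"cannot realize separation {separation} for "
                f"{n_clusters} centers in {n} dimensions"
            )
        centers *= separation / min_dist

    cluster_id = rng.integers(0, n_clusters, size=m)
    informative = np.sort(rng.choice(n, size=n_informative, replace=False))

    values = np.empty((m, n))
    score = np.empty(m)
    base_w = rng.standard_normal(n_informative)
    base_w /= np.linalg.norm(base_w)
    for c in range(n_clusters):
        rows = np.flatnonzero(cluster_id == c)
        if rows.size == 0:
            continue
        loadings, _ = np.linalg.qr(rng.standard_normal((n, within_rank)))
        latent = rng.standard_normal((rows.size, within_rank))
        factor_part = factor_sd * latent @ loadings.T
        deviation = factor_part + rng.normal(0.0, noise_sd, size=(rows.size, n))
        values[rows] = centers[c] + deviation
        s = deviation[:, informative] @ (base_w * (-1.0) ** c)
        if rows.size > 1 and s.std() > 0:
            s = (s - s.mean()) / s.std()
        score[rows] = s

    intercept = label_sharpness * norm.ppf(np.clip(class_balance, 1e-12, 1 - 1e-12))
    posterior = expit(label_sharpness * score + intercept)
    labels = (rng.random(m) < posterior).astype(int)

    rates = np.zeros(n)
    if missing_rates is not None:
        if isinstance(missing_rates, Mapping):
            for name, rate in missing_rates.items():
                rates[names.index(name)] = rate
        else:
            rates = np.asarray(missing_rates, dtype=float)
            if rates.shape != (n,):
                raise ValueError("missing_rates must have one entry per column")
    if (rates < 0).any() or (rates >= 1).any():
        raise ValueError("missing rates must lie in [0, 1)")
    mask = rng.random((m, n)) < rates[None, :]

    true_values = np.full((m, n), np.nan)
    true_values[mask] = values[mask]
    masked_values = values.copy()
    masked_values[mask] = 0.0

    table = FeatureTable(masked_values, names, mask, labels)
    truth = SyntheticTruth(
        true_values=true_values,
        true_cluster_id=cluster_id + 1,
        true_informative_features=tuple(names[j] for j in informative),
        seed=seed,
        params={
            "m": m,
            "n": n,
            "n_clusters": n_clusters,
            "separation": separation,
            "class_balance": class_balance,
            "noise_sd": noise_sd,
            "factor_sd": factor_sd,
            "within_rank": within_rank,
            "label_sharpness": label_sharpness,
        },
    )
    return table, truth


def _exact_moments(
    draws: np.ndarray, mean: float, sd: float
) -> np.ndarray:
    """Affine-map a sample so its mean and sample SD equal the targets exactly."""
    z = (draws - draws.mean()) / draws.std(ddof=1)
    return mean + sd * z


def generate_pima_like_cohort(seed: int = 0) -> tuple[FeatureTable, SyntheticTruth]:
    """Synthetic stand-in for the public diabetes-screening cohort.

    Plants, exactly: 768 records; 268 diabetic / 500 control; the published
    per-column zero-sentinel counts (glucose 5, blood pressure 35, skinfold
    227, insulin 374, BMI 27); and the published per-column mean ± SD
    (computed before the zero sentinels are written, so the unmasked
    pregnancies column matches 3.84 ± 3.36 by construction).  Skewed
    nonnegative measurements (pregnancy count, skinfold, insulin, pedigree,
    age) use standardized exponential deviates so the affine moment match
    cannot produce negative values; the rest use normal deviates.  Diabetic
    records get an upward shift on glucose, insulin, BMI, age and pregnancy
    count before the moment match, giving the outcome a realistic signal.
    """
    rng = np.random.default_rng(seed)
    m = PIMA_N_RECORDS
    labels = np.zeros(m, dtype=int)
    labels[rng.choice(m, size=PIMA_N_CASES, replace=False)] = 1

    skewed = {"pregnancies", "skin_thickness", "insulin", "pedigree", "age"}
    class_shift = {  # standardized-units uplift for diabetic records
        "pregnancies": 0.35,
        "glucose": 0.9,
        "insulin": 0.5,
        "bmi": 0.45,
        "age": 0.35,
    }
    values = np.empty((m, len(PIMA_FEATURES)))
    for j, name in enumerate(PIMA_FEATURES):
        if name in skewed:
            draws = rng.exponential(1.0, size=m)
        else:
            draws = rng.standard_normal(m)
        draws = draws + class_shift.get(name, 0.0) * labels
        mean, sd = PIMA_MOMENTS[name]
        values[:, j] = _exact_moments(draws, mean, sd)

    mask = np.zeros(values.shape, dtype=bool)
    true_values = np.full(values.shape, np.nan)
    for name, count in PIMA_ZERO_COUNTS.items():
        j = PIMA_FEATURES.index(name)
        rows = rng.choice(m, size=count, replace=False)
        true_values[rows, j] = values[rows, j]
        values[rows, j] = 0.0
        mask[rows, j] = True

    table = FeatureTable(values, PIMA_FEATURES, np.zeros_like(mask), labels)
    truth = SyntheticTruth(
        true_values=true_values,
        true_cluster_id=np.ones(m, dtype=int),
        true_informative_features=("glucose", "insulin", "bmi", "age", "pregnancies"),
        seed=seed,
        params={"m": m, "n_cases": PIMA_N_CASES, "zero_counts": PIMA_ZERO_COUNTS},
    )
    return table, truth
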