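"""End-to-end diagnosis pipeline: mask → normalize → PCA → SOM →
per-cluster SVD imputation → per-cluster feature selection → per-cluster
DBN ensembles.

The user-facing surface follows the model/results idiom:
:class:`DiabetesEnsemble` holds the data and configuration; ``fit()``
returns an :class:`EnsembleResults` carrying every fitted artifact
(scalers, PCA, SOM grid, per-cluster imputation statistics, selected
features and subnetworks) plus ``predict``, ``evaluate`` and ``summary``.

Clustering precedes imputation: the SOM runs on z-scored (optionally
PCA-projected) records with a temporary column-mean fill at missing
cells, then each cluster's submatrix is imputed in the original feature
space.  Classification is one-class–one-network: each cluster carries one
one-vs-rest logistic-output DBN per class, coordinated by argmax (ties go
to class 0).  Clusters too small to support their own models use a global
fallback DBN trained on all records.  Everything fitted — including
prediction-time imputation — uses training data only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from . import dbn as dbn_mod
from . import pca_denoise, som_cluster, stepdisc, svd_impute
from .data_io import DEFAULT_MISSING_COLUMNS, FeatureTable, mask_zeros_as_missing

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ClusterModel",
    "Predictions",
    "ConfusionMatrix",
    "EnsembleResults",
    "DiabetesEnsemble",
    "holdout_split",
    "evaluate",
    "accuracy_over_seeds",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, serializable as YAML/JSON.

    Defaults: the five zero-sentinel columns; PCA retaining 90 % variance;
    a 2×3 SOM (six clusters); rank-2 SVD imputation; backward stepwise
    selection at stay level 0.15; two hidden layers (16, 8) trained with
    batch size 100 for 200 epochs; stratified 70/30 holdout.
    """

    missing_columns: tuple[str, ...] = DEFAULT_MISSING_COLUMNS
    use_pca: bool = True
    pca_k: float = 0.90
    som_rows: int = 2
    som_cols: int = 3
    som_epochs: int = 200
    imputer: str = "svd"  # "svd" or "mean"
    impute_d: int = 2
    impute_tol: float = 1e-4
    impute_max_iter: int = 100
    use_stepdisc: bool = True
    stepdisc_alpha: float = 0.15
    dbn_hidden: tuple[int, ...] = (16, 8)
    dbn_epochs: int = 200
    dbn_batch_size: int = 100
    pretrain_lr: float = 0.1
    pretrain_momentum: float = 0.5
    finetune_lr: float = 0.2
    finetune_restarts: int = 2
    subnetwork_outputs: int = 1
    test_fraction: float = 0.3
    min_cluster_size: int = 20
    seed: int = 42

    def __post_init__(self) -> None:
        if self.imputer not in ("svd", "mean"):
            raise ValueError("imputer must be 'svd' or 'mean'")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["missing_columns"] = list(self.missing_columns)
        payload["dbn_hidden"] = list(self.dbn_hidden)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "missing_columns" in payload:
            payload["missing_columns"] = tuple(payload["missing_columns"])
        if "dbn_hidden" in payload:
            payload["dbn_hidden"] = tuple(payload["dbn_hidden"])
        return cls(**payload)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or "\n" not in str(source):
            source = Path(source).read_text()
        return cls.from_dict(yaml.safe_load(source))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; accuracy = (TP + TN) / total."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def evaluate(predicted: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Confusion matrix of predicted vs true binary labels."""
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    return ConfusionMatrix(
        tp=int(((predicted == 1) & (truth == 1)).sum()),
        fn=int(((predicted == 0) & (truth == 1)).sum()),
        fp=int(((predicted == 1) & (truth == 0)).sum()),
        tn=int(((predicted == 0) & (truth == 0)).sum()),
    )


def holdout_split(
    table: FeatureTable, test_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split, reproducible per seed."""
    if table.labels is None:
        raise ValueError("holdout_split needs labels")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_rows: list[np.ndarray] = []
    train_rows: list[np.ndarray] = []
    for cls in (0, 1):
        idx = np.flatnonzero(table.labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 records")
        n_test = int(round(test_fraction * idx.size))
        if n_test == 0 or n_test == idx.size:
            raise ValueError(
                f"test_fraction {test_fraction} leaves class {cls} empty on one side"
            )
        idx = rng.permutation(idx)
        test_rows.append(idx[:n_test])
        train_rows.append(idx[n_test:])
    train = np.sort(np.concatenate(train_rows))
    test = np.sort(np.concatenate(test_rows))
    return table.take(train), table.take(test)


@dataclass(frozen=True)
class ClusterModel:
    """Per-cluster fitted artifacts (or a fallback marker).

    ``col_means``/``col_sds`` are the cluster's observed-cell statistics in
    the original feature space; ``vt_d`` is the rank-d row-space basis of
    the cluster's imputed z-score matrix, reused to impute incoming
    records without refitting.
    """

    unit: int
    n_train: int
    fallback: bool
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None
    vt_d: np.ndarray | None = None
    selected: tuple[int, ...] = ()
    scaler_min: np.ndarray | None = None
    scaler_range: np.ndarray | None = None
    networks: dict[int, dbn_mod.DBNModel] | None = None

    def impute_records(
        self, values: np.ndarray, mask: np.ndarray
    ) -> np.ndarray:
        """Fill missing cells from stored cluster statistics only."""
        filled = values.copy()
        if not mask.any():
            return filled
        if self.vt_d is None:
            filled[mask] = np.broadcast_to(
                self.col_means[None, :], values.shape
            )[mask]
            return filled
        # least-squares fit of the rank-d coefficients on the observed
        # coordinates, then reconstruction of the missing ones; this is the
        # exact conditional completion in the stored basis
        z = (values - self.col_means[None, :]) / self.col_sds[None, :]
        for i in np.flatnonzero(mask.any(axis=1)):
            miss = mask[i]
            obs = ~miss
            if not obs.any():
                filled[i, miss] = self.col_means[miss]
                continue
            coef, *_ = np.linalg.lstsq(
                self.vt_d[:, obs].T, z[i, obs], rcond=None
            )
            filled[i, miss] = (
                self.col_means[miss] + self.col_sds[miss] * (coef @ self.vt_d[:, miss])
            )
        return filled


@dataclass(frozen=True)
class Predictions:
    """Predicted labels, routed cluster unit, and class-1 probability."""

    labels: np.ndarray
    cluster_id: np.ndarray
    proba: np.ndarray


def _minmax_scale(
    X: np.ndarray, lo: np.ndarray, rng_: np.ndarray
) -> np.ndarray:
    return np.clip((X - lo[None, :]) / rng_[None, :], 0.0, 1.0)


class DiabetesEnsemble:
    """The combined-diagnosis model, bound to a labeled feature table.

    Parameters
    ----------
    table : FeatureTable
        Training data (labels required for ``fit``).
    config : PipelineConfig, optional
        Defaults reproduce the reference configuration (2×3 SOM, rank-2
        imputation, two-hidden-layer DBNs).
    """

    def __init__(self, table: FeatureTable, config: PipelineConfig | None = None):
        self.table = table
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        frame,
        label_column: str = "outcome",
        config: PipelineConfig | None = None,
    ) -> "DiabetesEnsemble":
        features = [c for c in frame.columns if c != label_column]
        table = FeatureTable(
            frame[features].to_numpy(dtype=float),
            tuple(features),
            None,
            frame[label_column].to_numpy() if label_column in frame else None,
        )
        return cls(table, config)

    # ------------------------------------------------------------------ fit

    def fit(self) -> "EnsembleResults":
        cfg = self.config
        if self.table.labels is None:
            raise ValueError("fit requires labels")
        table = mask_zeros_as_missing(self.table, cfg.missing_columns)
        if not table.missing_mask.any():
            logger.info("no missing cells; imputation stages are no-ops")
        norm = svd_impute.normalize(table.values, table.missing_mask)
        features = norm.Z
        pca_model = None
        if cfg.use_pca:
            pca_model = pca_denoise.fit_pca(features, cfg.pca_k)
            features = pca_denoise.transform(pca_model, features)
        grid = som_cluster.init_grid(
            cfg.som_rows, cfg.som_cols, features.shape[1], features, cfg.seed
        )
        grid = som_cluster.train(grid, features, cfg.som_epochs)
        assignment = som_cluster.assign_clusters(grid, features)

        seed_rng = np.random.default_rng(cfg.seed)
        global_model = self._fit_cluster(
            table, np.arange(table.m), unit=-1, cfg=cfg, seed_rng=seed_rng,
            allow_fallback=False,
        )
        clusters: dict[int, ClusterModel] = {}
        for unit in range(grid.n_units):
            rows = np.flatnonzero(assignment.unit_index == unit)
            if rows.size == 0:
                clusters[unit] = ClusterModel(
                    unit=unit, n_train=0, fallback=True
                )
                continue
            clusters[unit] = self._fit_cluster(
                table, rows, unit=unit, cfg=cfg, seed_rng=seed_rng,
                allow_fallback=True,
            )

        results = EnsembleResults(
            config=cfg,
            feature_names=table.feature_names,
            norm_params=norm.params,
            pca_model=pca_model,
            grid=grid,
            clusters=clusters,
            global_model=global_model,
            manifest={
                "seed": cfg.seed,
                "n_train": table.m,
                "cluster_sizes": assignment.counts.tolist(),
                "config": cfg.to_dict(),
                "pca_components": None if pca_model is None else pca_model.k,
                "som_inputs": "pca_scores" if cfg.use_pca else "zscores",
                "temporary_fill": "column_mean",
            },
        )
        train_pred = results.predict(self.table)
        results.manifest["train_accuracy"] = evaluate(
            train_pred.labels, self.table.labels
        ).accuracy
        return results

    def _fit_cluster(
        self,
        table: FeatureTable,
        rows: np.ndarray,
        unit: int,
        cfg: PipelineConfig,
        seed_rng: np.random.Generator,
        allow_fallback: bool,
    ) -> ClusterModel:
        values = table.values[rows]
        mask = table.missing_mask[rows]
        labels = table.labels[rows]
        n = rows.size
        classes, counts = np.unique(labels, return_counts=True)
        degenerate = classes.size < 2 or counts.min() < 2
        if allow_fallback and (n < cfg.min_cluster_size or degenerate):
            logger.info(
                "cluster %d (%d records) below threshold or single-class; "
                "using global fallback",
                unit,
                n,
            )
            return ClusterModel(unit=unit, n_train=n, fallback=True)
        if degenerate:
            raise ValueError(
                f"cluster {unit}: need both classes with >= 2 records"
            )

        # --- imputation in the original feature space
        observed = ~mask
        col_means = np.empty(table.n)
        col_sds = np.ones(table.n)
        for j in range(table.n):
            col = values[observed[:, j], j]
            col_means[j] = col.mean() if col.size else np.nan
        enough = (observed.sum(axis=0) >= 2).all()
        vt_d = None
        d = min(cfg.impute_d, n, table.n)
        if cfg.imputer == "svd" and enough and n >= cfg.impute_d + 2:
            # a handful of boundary records from a neighbouring cluster sit
            # ~1 centre-separation away and would hijack the rank-d basis;
            # estimate the imputation statistics on a trimmed core
            obs_params = svd_impute.normalize(values, mask).params
            z0 = (values - obs_params.mean[None, :]) / obs_params.sd[None, :]
            z0[mask] = 0.0
            n_obs = np.maximum(observed.sum(axis=1), 1)
            dist = np.sqrt((z0**2).sum(axis=1) / n_obs)
            keep = dist <= 2.5 * np.median(dist)
            if keep.sum() < cfg.impute_d + 2 or (
                (~mask[keep]).sum(axis=0) < 2
            ).any():
                keep = np.ones(n, dtype=bool)
            em_filled, _ = svd_impute.impute(
                values[keep], mask[keep], d, cfg.impute_tol, cfg.impute_max_iter
            )
            norm_c = svd_impute.normalize(values[keep], mask[keep])
            col_means = norm_c.params.mean
            col_sds = norm_c.params.sd
            z_filled = (em_filled - col_means[None, :]) / col_sds[None, :]
            vt_d = svd_impute.rank_d_approximation(z_filled, d).vt
        else:
            if cfg.imputer == "svd":
                warnings.warn(
                    f"cluster {unit}: too small for rank-{cfg.impute_d} "
                    "imputation; falling back to column means",
                    stacklevel=2,
                )
            for j in range(table.n):
                col = values[observed[:, j], j]
                col_sds[j] = col.std(ddof=1) if col.size > 1 else 1.0
            if np.isnan(col_means).any():
                global_means = np.nanmean(
                    np.where(table.missing_mask, np.nan, table.values), axis=0
                )
                col_means = np.where(np.isnan(col_means), global_means, col_means)
            col_sds = np.where(col_sds == 0, 1.0, col_sds)

        # all downstream stages see exactly the imputation a scored record
        # gets at prediction time (stored statistics + stored basis), so
        # training and serving cannot drift apart
        stats_model = ClusterModel(
            unit=unit,
            n_train=n,
            fallback=False,
            col_means=col_means,
            col_sds=col_sds,
            vt_d=vt_d,
        )
        filled = stats_model.impute_records(values, mask)

        # --- backward stepwise feature selection on the imputed submatrix
        selected = tuple(range(table.n))
        if cfg.use_stepdisc:
            try:
                selected = stepdisc.backward_select(
                    filled, labels, cfg.stepdisc_alpha
                ).selected
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning(
                    "cluster %d: stepwise selection failed (%s); keeping all "
                    "features",
                    unit,
                    exc,
                )

        # --- one one-vs-rest DBN per class on min-max-scaled features
        sub = filled[:, selected]
        lo = sub.min(axis=0)
        rng_ = sub.max(axis=0) - lo
        rng_ = np.where(rng_ == 0, 1.0, rng_)
        X01 = _minmax_scale(sub, lo, rng_)
        layer_sizes = (len(selected), *cfg.dbn_hidden)
        networks: dict[int, dbn_mod.DBNModel] = {}
        for cls in (0, 1):
            # an unlucky pretraining draw can leave a stack whose unrolled
            # network stalls at the base rate for the whole training run;
            # train independent (pretrain, fine-tune) pairs, keep the lowest
            # final loss, and retry (bounded) while the best run is not
            # meaningfully below the best constant predictor's loss
            target = (labels == cls).astype(int)
            rate = float(np.clip(target.mean(), 1e-9, 1 - 1e-9))
            base_entropy = -(
                rate * np.log(rate) + (1 - rate) * np.log(1 - rate)
            )
            best = None
            max_attempts = max(1, cfg.finetune_restarts) + 4
            for attempt in range(max_attempts):
                sub_seed = int(seed_rng.integers(2**31))
                stack = dbn_mod.pretrain_stack(
                    layer_sizes,
                    X01,
                    epochs=cfg.dbn_epochs,
                    batch_size=cfg.dbn_batch_size,
                    lr=cfg.pretrain_lr,
                    momentum=cfg.pretrain_momentum,
                    seed=sub_seed,
                )
                net = dbn_mod.fine_tune(
                    stack,
                    X01,
                    target,
                    epochs=cfg.dbn_epochs,
                    batch_size=cfg.dbn_batch_size,
                    lr=cfg.finetune_lr,
                    seed=sub_seed + 1,
                    n_outputs=cfg.subnetwork_outputs,
                )
                if best is None or net.loss_history[-1] < best.loss_history[-1]:
                    best = net
                stalled = best.loss_history[-1] > 0.8 * base_entropy
                if attempt + 1 >= max(1, cfg.finetune_restarts) and not stalled:
                    break
            networks[cls] = best
        return ClusterModel(
            unit=unit,
            n_train=n,
            fallback=False,
            col_means=col_means,
            col_sds=col_sds,
            vt_d=vt_d,
            selected=selected,
            scaler_min=lo,
            scaler_range=rng_,
            networks=networks,
        )


@dataclass
class EnsembleResults:
    """Fitted pipeline: every artifact needed to score new records."""

    config: PipelineConfig
    feature_names: tuple[str, ...]
    norm_params: svd_impute.NormalizationParams
    pca_model: pca_denoise.PCAModel | None
    grid: som_cluster.SOMGrid
    clusters: dict[int, ClusterModel]
    global_model: ClusterModel
    manifest: dict = field(default_factory=dict)

    # -------------------------------------------------------------- predict

    def predict(self, table: FeatureTable) -> Predictions:
        if table.feature_names != self.feature_names:
            raise ValueError("schema mismatch with the training table")
        cfg = self.config
        masked = mask_zeros_as_missing(table, cfg.missing_columns)
        Z = (masked.values - self.norm_params.mean[None, :]) / self.norm_params.sd[
            None, :
        ]
        Z[masked.missing_mask] = 0.0
        features = Z
        if self.pca_model is not None:
            features = pca_denoise.transform(self.pca_model, features)
        assignment = som_cluster.assign_clusters(self.grid, features)
        labels = np.empty(table.m, dtype=int)
        proba = np.empty(table.m)
        for unit in np.unique(assignment.unit_index):
            rows = np.flatnonzero(assignment.unit_index == unit)
            model = self.clusters.get(int(unit))
            if model is None or model.fallback:
                model = self.global_model
            filled = model.impute_records(
                masked.values[rows], masked.missing_mask[rows]
            )
            sub = filled[:, model.selected]
            X01 = _minmax_scale(sub, model.scaler_min, model.scaler_range)
            score0 = dbn_mod.predict_proba(model.networks[0], X01)
            score1 = dbn_mod.predict_proba(model.networks[1], X01)
            labels[rows] = (score1 > score0).astype(int)  # tie -> class 0
            proba[rows] = score1 / (score0 + score1)
        return Predictions(
            labels=labels, cluster_id=assignment.unit_index, proba=proba
        )

    def evaluate(self, table: FeatureTable) -> ConfusionMatrix:
        if table.labels is None:
            raise ValueError("evaluate requires labels")
        return evaluate(self.predict(table).labels, table.labels)

    # -------------------------------------------------------------- summary

    def summary(self) -> str:
        lines = [
            "Combined diagnosis ensemble (SVD impute + SOM + STEPDISC + DBN)",
            "=" * 64,
            f"records (train): {self.manifest.get('n_train')}",
            f"SOM grid: {self.grid.rows}x{self.grid.cols} "
            f"({self.grid.n_units} clusters), epochs {self.grid.epochs_trained}",
            f"PCA components: {self.manifest.get('pca_components')}",
            f"imputer: {self.config.imputer} (d={self.config.impute_d})",
            f"stepwise alpha: {self.config.stepdisc_alpha}",
            f"DBN hidden layers: {self.config.dbn_hidden}, "
            f"epochs {self.config.dbn_epochs}, batch {self.config.dbn_batch_size}",
            "-" * 64,
            f"{'unit':>4} {'n':>6} {'model':>8}  selected features",
        ]
        for unit in sorted(self.clusters):
            cm = self.clusters[unit]
            kind = "fallback" if cm.fallback else "own"
            names = (
                ", ".join(self.feature_names[j] for j in cm.selected)
                if not cm.fallback
                else "-"
            )
            lines.append(f"{unit:>4} {cm.n_train:>6} {kind:>8}  {names}")
        if "train_accuracy" in self.manifest:
            lines.append("-" * 64)
            lines.append(
                f"training accuracy: {self.manifest['train_accuracy']:.4f}"
            )
        return "\n".join(lines)

    # ---------------------------------------------------------- persistence

    def to_json(self, path: str | Path | None = None) -> str:
        def cluster_payload(cm: ClusterModel) -> dict:
            return {
                "unit": cm.unit,
                "n_train": cm.n_train,
                "fallback": cm.fallback,
                "col_means": None if cm.col_means is None else cm.col_means.tolist(),
                "col_sds": None if cm.col_sds is None else cm.col_sds.tolist(),
                "vt_d": None if cm.vt_d is None else cm.vt_d.tolist(),
                "selected": list(cm.selected),
                "scaler_min": None
                if cm.scaler_min is None
                else cm.scaler_min.tolist(),
                "scaler_range": None
                if cm.scaler_range is None
                else cm.scaler_range.tolist(),
                "networks": None
                if cm.networks is None
                else {
                    str(cls): net.to_jsonable() for cls, net in cm.networks.items()
                },
            }

        payload = {
            "config": self.config.to_dict(),
            "feature_names": list(self.feature_names),
            "norm_mean": self.norm_params.mean.tolist(),
            "norm_sd": self.norm_params.sd.tolist(),
            "pca": None
            if self.pca_model is None
            else {
                "components": self.pca_model.components.tolist(),
                "explained_variance": self.pca_model.explained_variance.tolist(),
                "explained_variance_ratio": self.pca_model.explained_variance_ratio.tolist(),
                "mean": self.pca_model.mean.tolist(),
            },
            "grid": json.loads(self.grid.to_json()),
            "clusters": {str(u): cluster_payload(c) for u, c in self.clusters.items()},
            "global_model": cluster_payload(self.global_model),
            "manifest": self.manifest,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EnsembleResults":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            source = Path(source).read_text()
        payload = json.loads(source)

        def cluster_from(d: dict) -> ClusterModel:
            arr = lambda v: None if v is None else np.asarray(v, dtype=float)
            return ClusterModel(
                unit=d["unit"],
                n_train=d["n_train"],
                fallback=d["fallback"],
                col_means=arr(d["col_means"]),
                col_sds=arr(d["col_sds"]),
                vt_d=arr(d["vt_d"]),
                selected=tuple(d["selected"]),
                scaler_min=arr(d["scaler_min"]),
                scaler_range=arr(d["scaler_range"]),
                networks=None
                if d["networks"] is None
                else {
                    int(k): dbn_mod.DBNModel.from_jsonable(v)
                    for k, v in d["networks"].items()
                },
            )

        grid_payload = payload["grid"]
        grid_payload["weights"] = np.asarray(grid_payload["weights"], dtype=float)
        pca_model = None
        if payload["pca"] is not None:
            p = payload["pca"]
            pca_model = pca_denoise.PCAModel(
                components=np.asarray(p["components"], dtype=float),
                explained_variance=np.asarray(p["explained_variance"], dtype=float),
                explained_variance_ratio=np.asarray(
                    p["explained_variance_ratio"], dtype=float
                ),
                mean=np.asarray(p["mean"], dtype=float),
            )
        return cls(
            config=PipelineConfig.from_dict(payload["config"]),
            feature_names=tuple(payload["feature_names"]),
            norm_params=svd_impute.NormalizationParams(
                mean=np.asarray(payload["norm_mean"], dtype=float),
                sd=np.asarray(payload["norm_sd"], dtype=float),
            ),
            pca_model=pca_model,
            grid=som_cluster.SOMGrid(**grid_payload),
            clusters={
                int(k): cluster_from(v) for k, v in payload["clusters"].items()
            },
            global_model=cluster_from(payload["global_model"]),
            manifest=payload["manifest"],
        )


def accuracy_over_seeds(
    make_table: Callable[[int], FeatureTable],
    config: PipelineConfig,
    seeds: Sequence[int],
) -> np.ndarray:
    """Holdout accuracy of the pipeline across replicate seeds.

    ``make_table(seed)`` supplies the data; the same seed drives the
    stratified split and all pipeline randomness, so replicates are fully
    reproducible.
    """
    accuracies = []
    for seed in seeds:
        table = make_table(seed)
        cfg = PipelineConfig.from_dict({**config.to_dict(), "seed": seed})
        train, test = holdout_split(table, cfg.test_fraction, seed)
        results = DiabetesEnsemble(train, cfg).fit()
        accuracies.append(results.evaluate(test).accuracy)
    return np.asarray(accuracies)
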