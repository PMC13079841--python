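"""Evaluation metrics and protocols.

Classification quality on labeled data (accuracy, support-weighted F1) and
internal clustering quality of the integrated latent space (Silhouette,
Davies-Bouldin).  The two evaluation modes for target data mirror common
practice: ``pred`` treats each predicted class as a cluster; ``kmeans``
clusters the latent coordinates with K set to the known class count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, f1_score, silhouette_score
from sklearn.model_selection import StratifiedKFold

from .core_data import EmbeddingResult, MultiOmicsDataset


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of exactly matching labels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return float((pred == truth).mean())


def weighted_f1(pred: np.ndarray, truth: np.ndarray, K: int) -> float:
    """Per-class F1 averaged with true-class support weights; classes absent
    from the truth contribute 0 with weight 0."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    labels = list(range(1, K + 1))
    return float(f1_score(truth, pred, labels=labels, average="weighted", zero_division=0))


def _check_clusters(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")


def silhouette(latent: np.ndarray, cluster_labels: np.ndarray) -> float:
    """Mean silhouette width with Euclidean distances (singleton clusters
    score 0 for their sample)."""
    latent = np.asarray(latent, dtype=float)
    cluster_labels = np.asarray(cluster_labels)
    _check_clusters(cluster_labels)
    if latent.shape[0] < 3:
        raise ValueError("need n >= 3 samples")
    return float(silhouette_score(latent, cluster_labels, metric="euclidean"))


def davies_bouldin(latent: np.ndarray, cluster_labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case ratio of
    summed intra-cluster dispersions to centroid distance (lower is better)."""
    latent = np.asarray(latent, dtype=float)
    cluster_labels = np.asarray(cluster_labels)
    _check_clusters(cluster_labels)
    return float(davies_bouldin_score(latent, cluster_labels))


@dataclass
class TargetMetrics:
    mode: str
    silhouette: Optional[float]
    dbi: Optional[float]
    cluster_labels: Optional[np.ndarray] = None


def evaluate_target(
    result: EmbeddingResult, K: int, mode: str = "pred", seed: int = 0
) -> TargetMetrics:
    """Clustering quality of a target embedding.

    ``pred`` mode uses the model's predicted labels as clusters (undefined,
    with a warning, if predictions collapse to fewer than 2 classes);
    ``kmeans`` mode runs seeded K-means (k-means++, 10 restarts) with the
    known class count on the latent coordinates.
    """
    if mode == "pred":
        labels = result.predicted_labels
        if len(np.unique(labels)) < 2:
            warnings.warn("predictions collapsed to one class; metrics undefined", stacklevel=2)
            return TargetMetrics("pred", None, None, labels)
    elif mode == "kmeans":
        km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(result.latent)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TargetMetrics(
        mode,
        silhouette(result.latent, labels),
        davies_bouldin(result.latent, labels),
        np.asarray(labels),
    )


def crossval_source(
    source: MultiOmicsDataset,
    target: MultiOmicsDataset,
    config=None,
    folds: int = 5,
) -> list[dict]:
    """Stratified K-fold protocol on the labeled source: each fold trains the
    full pipeline on the remaining source samples (target unchanged) and
    scores accuracy / weighted F1 on the held-out source fold."""
    from .trainer import TrainConfig, fit, predict

    config = config or TrainConfig()
    if source.labels is None:
        raise ValueError("crossval_source requires a labeled source")
    counts = np.bincount(source.labels)[1:]
    if (counts < folds).any():
        small = [i + 1 for i, c in enumerate(counts) if c < folds]
        raise ValueError(
            f"class(es) {small} have fewer than {folds} samples; reduce folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    sample_ids = source.sample_ids
    records = []
    for fold, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(source.n_samples), source.labels)
    ):
        train_ids = [sample_ids[i] for i in train_idx]
        test_ids = [sample_ids[i] for i in test_idx]
        train_set = MultiOmicsDataset(
            [m.subset_samples(train_ids) for m in source.matrices],
            domain=source.domain,
            labels=source.labels[train_idx],
            class_names=source.class_names,
        )
        test_set = MultiOmicsDataset(
            [m.subset_samples(test_ids) for m in source.matrices],
            domain=source.domain,
            labels=None,
            class_names=source.class_names,
        )
        bundle, _ = fit(train_set, target, config)
        pred = predict(bundle, test_set).predicted_labels
        truth = source.labels[test_idx]
        records.append(
            {
                "fold": fold,
                "accuracy": accuracy(pred, truth),
                "weighted_f1": weighted_f1(pred, truth, source.n_classes),
                "n_test": len(test_idx),
            }
        )
    return records


def metric_table(records: list[dict], task: str = "task", seed: int = 0):
    """Tidy (task, mode, metric, value, seed, fold) table from metric records."""
    import pandas as pd

    rows = []
    for rec in records:
        fold = rec.get("fold", "")
        mode = rec.get("mode", "")
        for key, val in rec.items():
            if key in ("fold", "mode", "n_test", "cluster_labels"):
                continue
            rows.append(
                {"task": task, "mode": mode, "metric": key, "value": val,
                 "seed": seed, "fold": fold}
            )
    return pd.DataFrame(rows)
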