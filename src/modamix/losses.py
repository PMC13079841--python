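"""Training objectives as pure, separately testable numpy functions.

These implement the supervised cross-entropy of the pre-training phase, the
adversarial domain objectives (discriminator loss and its negation for the
extractor), the semi-supervised pseudo-label objective with its epoch-ramped
balancing coefficient, and the class-centroid alignment penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

LOG_CLAMP = 1e-12


@dataclass
class ScheduleParams:
    """Ramp schedule for the pseudo-label balancing coefficient alpha(t):
    0 before epoch T1, linear from 0 to alpha_f on [T1, T2), alpha_f after."""

    T1: int = 100
    T2: int = 200
    alpha_f: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.T1 < self.T2):
            raise ValueError("need 0 <= T1 < T2")
        if self.alpha_f < 0:
            raise ValueError("alpha_f must be >= 0")


def _check_pair(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: posteriors {p.shape} vs targets {y.shape}")
    return p, y


def cross_entropy(posteriors: np.ndarray, onehot: np.ndarray) -> float:
    """Mean cross-entropy -(1/n) sum_i sum_k y_ik log p_ik, with p clamped
    at 1e-12 before the log."""
    p, y = _check_pair(posteriors, onehot)
    return float(-(y * np.log(np.maximum(p, LOG_CLAMP))).sum() / p.shape[0])


def domain_discriminator_loss(domain_posteriors: np.ndarray, domain_onehot: np.ndarray) -> float:
    """Cross-entropy over the two domain classes, averaged over the pooled
    source+target samples."""
    p, d = _check_pair(domain_posteriors, domain_onehot)
    if p.shape[1] != 2:
        raise ValueError("domain posteriors must have 2 columns (source, target)")
    return cross_entropy(p, d)


def extractor_confusion_loss(domain_posteriors: np.ndarray, domain_onehot: np.ndarray) -> float:
    """Negated discriminator loss: minimizing it maximizes the discriminator's
    error, realizing the extractor side of the adversarial min-max."""
    return -domain_discriminator_loss(domain_posteriors, domain_onehot)


def assign_pseudo_labels(
    posteriors: np.ndarray, confidence_threshold: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-label = posterior argmax (1-based; ties to the lowest class);
    keep_mask marks rows whose top posterior reaches the threshold."""
    p = np.asarray(posteriors, dtype=float)
    labels = np.argmax(p, axis=1) + 1
    keep = p.max(axis=1) >= confidence_threshold
    return labels, keep


def alpha_schedule(t: int, params: ScheduleParams | None = None) -> float:
    """Piecewise balancing coefficient at epoch ``t`` (see ScheduleParams)."""
    params = params or ScheduleParams()
    if t < params.T1:
        return 0.0
    if t < params.T2:
        return params.alpha_f * (t - params.T1) / (params.T2 - params.T1)
    return params.alpha_f


def ssl_loss(
    source_post: np.ndarray,
    source_onehot: np.ndarray,
    target_post: np.ndarray,
    target_pseudo_onehot: np.ndarray,
    keep_mask: np.ndarray,
    t: int,
    params: ScheduleParams | None = None,
) -> float:
    """Supervised source cross-entropy plus alpha(t)-weighted cross-entropy on
    the kept pseudo-labeled target rows (0 when no rows are kept)."""
    loss = cross_entropy(source_post, source_onehot)
    alpha = alpha_schedule(t, params)
    keep = np.asarray(keep_mask, dtype=bool)
    if alpha > 0 and keep.any():
        loss += alpha * cross_entropy(target_post[keep], target_pseudo_onehot[keep])
    return float(loss)


def centroid_alignment_loss(
    latent: np.ndarray,
    class_labels: np.ndarray,
    domain_labels: np.ndarray,
    K: int,
    M: int = 2,
) -> float:
    """(1/K) sum_k sum_m ||C^k - C^k_m||^2 between the pooled class centroid
    C^k and each domain-specific class centroid C^k_m.

    Empty (class, domain) cells contribute 0 — early in training pseudo-labels
    can miss classes entirely.
    """
    z = np.asarray(latent, dtype=float)
    cls = np.asarray(class_labels, dtype=int)
    dom = np.asarray(domain_labels, dtype=int)
    total = 0.0
    for k in range(1, K + 1):
        in_k = cls == k
        if not in_k.any():
            warnings.warn(f"class {k} has no samples; centroid term skipped", stacklevel=2)
            continue
        global_c = z[in_k].mean(axis=0)
        for m in range(1, M + 1):
            in_km = in_k & (dom == m)
            if not in_km.any():
                continue
            diff = global_c - z[in_km].mean(axis=0)
            total += float(diff @ diff)
    return total / K


def centroid_alignment_grad(
    latent: np.ndarray,
    class_labels: np.ndarray,
    domain_labels: np.ndarray,
    K: int,
    M: int = 2,
) -> np.ndarray:
    """Analytic gradient of :func:`centroid_alignment_loss` w.r.t. ``latent``."""
    z = np.asarray(latent, dtype=float)
    cls = np.asarray(class_labels, dtype=int)
    dom = np.asarray(domain_labels, dtype=int)
    grad = np.zeros_like(z)
    for k in range(1, K + 1):
        in_k = cls == k
        n_k = int(in_k.sum())
        if n_k == 0:
            continue
        global_c = z[in_k].mean(axis=0)
        for m in range(1, M + 1):
            in_km = in_k & (dom == m)
            n_km = int(in_km.sum())
            if n_km == 0:
                continue
            v = global_c - z[in_km].mean(axis=0)  # d-vector
            # d||v||^2 / dz_i = 2 v * (1/n_k [i in k] - 1/n_km [i in k,m])
            grad[in_k] += (2.0 / n_k) * v
            grad[in_km] -= (2.0 / n_km) * v
    return grad / K


def one_hot(labels: np.ndarray, K: int) -> np.ndarray:
    """1-based class indices to an n x K one-hot matrix."""
    lab = np.asarray(labels, dtype=int)
    if lab.min() < 1 or lab.max() > K:
        raise ValueError("labels must lie in {1..K}")
    out = np.zeros((len(lab), K), dtype=float)
    out[np.arange(len(lab)), lab - 1] = 1.0
    return out
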