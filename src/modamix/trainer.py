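"""Four-phase training orchestration.

Phase 1 pre-trains each per-modality extractor with its own classifier head
on the labeled source, then the shared extractor (with the per-modality
extractors frozen).  Phase 2 adversarially aligns source and target within
each modality (discriminator step, then extractor confusion step, per
iteration).  Phase 3 repeats the adversarial alignment on the integrated
latent with the shared discriminator.  Phase 4 refines extractors and the
final classifier jointly with the semi-supervised pseudo-label objective and
the class-centroid alignment penalty, refreshing pseudo-labels every epoch.

Batch-norm layers run in training mode (batch statistics) during all
optimization and in running-statistics mode for every reported embedding or
prediction, so inference is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from ._nn import Adam, Sequential, softmax
from .core_data import EmbeddingResult, MultiOmicsDataset
from .losses import (
    ScheduleParams,
    alpha_schedule,
    assign_pseudo_labels,
    centroid_alignment_grad,
    centroid_alignment_loss,
    cross_entropy,
    domain_discriminator_loss,
    one_hot,
)
from .networks import ModelBundle, build_bundle, classify, concat_single, forward_integrated

ABLATIONS = ("none", "no_at_multi", "no_at_all")


@dataclass
class TrainConfig:
    """All hyperparameters, schedules, ablation switches and the seed.

    Defaults are the published setting: 500 epochs for each of the first
    three phases and 800 for the final fine-tuning phase; Adam with learning
    rates 1e-4 (extractors), 1e-5 (classifiers) and 1e-6 (discriminators).
    """

    epochs_phase1: int = 500
    epochs_phase2: int = 500
    epochs_phase3: int = 500
    epochs_phase4: int = 800
    lr_extractor: float = 1e-4
    lr_classifier: float = 1e-5
    lr_discriminator: float = 1e-6
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    centroid_weight: float = 1.0
    batch_size: int | str = "full"
    adversarial_batch_size: int | str | None = None
    seed: int = 0
    ablation: str = "none"
    confidence_threshold: float = 0.0

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Reduced-schedule configuration for small cohorts (hundreds of
        samples): 100/100/100/200 epochs with learning rates rebalanced for
        the ~10^2-10^3 optimizer steps this implies.  The adversarial phases
        run on small minibatches so the discriminator/extractor game gets
        enough alternations to converge; the discriminator learning rate is
        raised so the discriminator stays near-optimal against the extractor,
        which the min-max formulation presumes."""
        params = dict(
            epochs_phase1=100, epochs_phase2=100, epochs_phase3=100, epochs_phase4=200,
            lr_extractor=1e-3, lr_classifier=1e-4, lr_discriminator=1e-2,
            adversarial_batch_size=16, seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if min(self.lr_extractor, self.lr_classifier, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be > 0")
        for e in (self.epochs_phase1, self.epochs_phase2, self.epochs_phase3, self.epochs_phase4):
            if e < 0:
                raise ValueError("epoch counts must be >= 0")


History = list[dict]


def _zero(*nets: Sequential) -> None:
    for net in nets:
        net.zero_grad()


def _batches(n: int, batch_size: int | str, rng: np.random.Generator) -> Iterator[np.ndarray]:
    if batch_size == "full" or int(batch_size) >= n:
        yield np.arange(n)
        return
    order = rng.permutation(n)
    b = int(batch_size)
    for start in range(0, n, b):
        yield order[start : start + b]


def _record(history: History, phase: int, epoch: int, name: str, value: float) -> None:
    history.append({"phase": phase, "epoch": epoch, "loss": name, "value": float(value)})


def _require_clean(dataset: MultiOmicsDataset, role: str) -> None:
    for mat in dataset.matrices:
        if mat.has_missing:
            raise ValueError(
                f"{role} modality {mat.modality!r} has missing values; "
                "impute during preprocessing before training"
            )


# ---------------------------------------------------------------------------
# phases
# ---------------------------------------------------------------------------

def phase1_pretrain(
    bundle: ModelBundle, source: MultiOmicsDataset, config: TrainConfig
) -> History:
    """Supervised pre-training on the labeled source."""
    if source.labels is None:
        raise ValueError("phase 1 requires a labeled source dataset")
    history: History = []
    rng = np.random.default_rng(config.seed * 4 + 1)
    Y = one_hot(source.labels, bundle.n_classes)
    Xs = source.arrays()

    for o in range(bundle.n_modalities):
        F, C = bundle.F[o], bundle.C_single[o]
        opt = Adam([(F.parameters(), config.lr_extractor), (C.parameters(), config.lr_classifier)])
        for epoch in range(config.epochs_phase1):
            losses, correct = [], 0
            for idx in _batches(source.n_samples, config.batch_size, rng):
                lat = F.forward(Xs[o][idx], train=True)
                p = softmax(C.forward(lat, train=True))
                losses.append(cross_entropy(p, Y[idx]))
                F.backward(C.backward((p - Y[idx]) / len(idx)))
                opt.step()
                _zero(F, C)
                correct += int((np.argmax(p, axis=1) + 1 == source.labels[idx]).sum())
            _record(history, 1, epoch, f"pretrain_ce_mod{o + 1}", float(np.mean(losses)))
            _record(history, 1, epoch, f"source_acc_mod{o + 1}", correct / source.n_samples)

    # shared extractor on frozen per-modality latents (running-stats mode)
    Z = concat_single(bundle, Xs, train=False)
    G, C = bundle.G, bundle.C_multi
    opt = Adam([(G.parameters(), config.lr_extractor), (C.parameters(), config.lr_classifier)])
    for epoch in range(config.epochs_phase1):
        losses, correct = [], 0
        for idx in _batches(source.n_samples, config.batch_size, rng):
            z = G.forward(Z[idx], train=True)
            p = softmax(C.forward(z, train=True))
            losses.append(cross_entropy(p, Y[idx]))
            G.backward(C.backward((p - Y[idx]) / len(idx)))
            opt.step()
            _zero(G, C)
            correct += int((np.argmax(p, axis=1) + 1 == source.labels[idx]).sum())
        _record(history, 1, epoch, "pretrain_ce_shared", float(np.mean(losses)))
        _record(history, 1, epoch, "source_acc_shared", correct / source.n_samples)
    return history


def _reinit_net(net: Sequential, rng: np.random.Generator, slope: float = 0.01) -> None:
    """Re-draw a network's parameters in place (Kaiming fan-in, fresh BN)."""
    from ._nn import BatchNorm, Linear

    for layer in net.layers:
        if isinstance(layer, Linear):
            n_in, n_out = layer.W.value.shape
            std = np.sqrt(2.0 / ((1.0 + slope**2) * n_in))
            layer.W.value[...] = rng.normal(0.0, std, size=(n_in, n_out))
            layer.b.value[...] = 0.0
        elif isinstance(layer, BatchNorm):
            layer.gamma.value[...] = 1.0
            layer.beta.value[...] = 0.0
            layer.running_mean[...] = 0.0
            layer.running_var[...] = 1.0


# if the discriminator's trailing mean loss falls this far below log 2, it is
# winning decisively and the extractor cannot catch up; re-initializing the
# discriminator gives the game a fresh trajectory (a standard remedy)
RESET_WINDOW = 10
RESET_FLOOR = 0.5


def _adversarial_phase(
    extractor: Sequential,
    discriminator: Sequential,
    X_pool: np.ndarray,
    d_onehot: np.ndarray,
    epochs: int,
    config: TrainConfig,
    rng: np.random.Generator,
    history: History,
    phase: int,
    tag: str,
) -> None:
    """One discriminator step then one extractor (confusion) step per iteration."""
    n = X_pool.shape[0]
    batch_size = config.adversarial_batch_size
    if batch_size is None:
        batch_size = config.batch_size
    opt_d = Adam([(discriminator.parameters(), config.lr_discriminator)])
    opt_f = Adam([(extractor.parameters(), config.lr_extractor)])
    recent: list[float] = []
    for epoch in range(epochs):
        d_losses = []
        for idx in _batches(n, batch_size, rng):
            # (a) discriminator minimizes the domain cross-entropy
            lat = extractor.forward(X_pool[idx], train=True)
            p = softmax(discriminator.forward(lat, train=True))
            d_losses.append(domain_discriminator_loss(p, d_onehot[idx]))
            discriminator.backward((p - d_onehot[idx]) / len(idx))
            opt_d.step()
            _zero(extractor, discriminator)
            # (b) extractor confusion step: drive D's posterior toward uniform.
            # This realizes the extractor side of the min-max: its minimum
            # coincides with the maximum of D's loss when D is near-optimal,
            # but unlike the raw negation it is non-saturating and its fixed
            # point is indistinguishability rather than confident error
            # (raw negation rewards making D confidently wrong, which swaps
            # the domains past each other instead of overlapping them).
            # The extractor did not change in (a), so its cached forward pass
            # is still valid; only the (cheap) discriminator is re-run.
            p = softmax(discriminator.forward(lat, train=True))
            grad_lat = discriminator.backward((p - 0.5) / len(idx))
            extractor.backward(grad_lat)
            opt_f.step()
            _zero(extractor, discriminator)
        _record(history, phase, epoch, f"disc_ce_{tag}", float(np.mean(d_losses)))
        recent.append(float(np.mean(d_losses)))
        if len(recent) >= RESET_WINDOW and np.mean(recent[-RESET_WINDOW:]) < RESET_FLOOR:
            _reinit_net(discriminator, rng)
            opt_d = Adam([(discriminator.parameters(), config.lr_discriminator)])
            recent = []
            _record(history, phase, epoch, f"disc_reset_{tag}", 1.0)


def phase2_single_omics_da(
    bundle: ModelBundle,
    source: MultiOmicsDataset,
    target: MultiOmicsDataset,
    config: TrainConfig,
) -> History:
    """Per-modality adversarial alignment of source and target latents."""
    history: History = []
    if config.ablation == "no_at_all":
        return history
    rng = np.random.default_rng(config.seed * 4 + 2)
    d_onehot = _domain_onehot(source.n_samples, target.n_samples)
    for o in range(bundle.n_modalities):
        X_pool = np.vstack([source.arrays()[o], target.arrays()[o]])
        _adversarial_phase(
            bundle.F[o], bundle.D_single[o], X_pool, d_onehot,
            config.epochs_phase2, config, rng, history, 2, f"mod{o + 1}",
        )
    return history


def phase3_multi_omics_da(
    bundle: ModelBundle,
    source: MultiOmicsDataset,
    target: MultiOmicsDataset,
    config: TrainConfig,
) -> History:
    """Adversarial alignment of the integrated latent with the shared
    discriminator; per-modality extractors stay frozen."""
    history: History = []
    if config.ablation in ("no_at_multi", "no_at_all"):
        return history
    rng = np.random.default_rng(config.seed * 4 + 3)
    Z_pool = np.vstack(
        [concat_single(bundle, source.arrays(), train=False),
         concat_single(bundle, target.arrays(), train=False)]
    )
    d_onehot = _domain_onehot(source.n_samples, target.n_samples)
    _adversarial_phase(
        bundle.G, bundle.D_shared, Z_pool, d_onehot,
        config.epochs_phase3, config, rng, history, 3, "shared",
    )
    return history


def _domain_onehot(n_s: int, n_t: int) -> np.ndarray:
    d = np.zeros((n_s + n_t, 2))
    d[:n_s, 0] = 1.0
    d[n_s:, 1] = 1.0
    return d


def phase4_semi_supervised(
    bundle: ModelBundle,
    source: MultiOmicsDataset,
    target: MultiOmicsDataset,
    config: TrainConfig,
) -> History:
    """Joint refinement of F, G and the final classifier with pseudo-labels,
    the ramped semi-supervised objective and centroid alignment."""
    if source.labels is None:
        raise ValueError("phase 4 requires a labeled source dataset")
    history: History = []
    K = bundle.n_classes
    n_s, n_t = source.n_samples, target.n_samples
    Y_s = one_hot(source.labels, K)
    X_pool = [np.vstack([xs, xt]) for xs, xt in zip(source.arrays(), target.arrays())]
    domains = np.concatenate([np.ones(n_s, dtype=int), np.full(n_t, 2, dtype=int)])
    params = [(net.parameters(), config.lr_extractor) for net in bundle.F]
    params.append((bundle.G.parameters(), config.lr_extractor))
    params.append((bundle.C_multi.parameters(), config.lr_classifier))
    opt = Adam(params)
    all_nets = [*bundle.F, bundle.G, bundle.C_multi]
    rng = np.random.default_rng(config.seed * 4 + 4)
    n = n_s + n_t

    for t in range(config.epochs_phase4):
        # refresh pseudo-labels from the current model (running-stats mode)
        z_t = forward_integrated(bundle, target.arrays(), train=False)
        p_t = classify(bundle.C_multi, z_t, train=False)
        pseudo, keep = assign_pseudo_labels(p_t, config.confidence_threshold)
        Y_pseudo = one_hot(pseudo, K)
        alpha = alpha_schedule(t, config.schedule)
        labels_all = np.concatenate([source.labels, pseudo])
        active_all = np.concatenate([np.ones(n_s, dtype=bool), keep])

        # with a zero pseudo-label weight and no centroid penalty the loss
        # has no target dependence: fine-tune on the source rows alone
        target_active = alpha > 0 or config.centroid_weight > 0
        n_train = n if target_active else n_s

        ce_s_sum = ce_t_sum = cent_sum = 0.0
        n_batches = 0
        for idx in _batches(n_train, config.batch_size, rng):
            is_src = idx < n_s
            lat_cat = concat_single(bundle, [X[idx] for X in X_pool], train=True)
            z = bundle.G.forward(lat_cat, train=True)
            p = softmax(bundle.C_multi.forward(z, train=True))

            grad_logits = np.zeros_like(p)
            src_rows = np.nonzero(is_src)[0]
            Y_b = Y_s[idx[src_rows]]
            grad_logits[src_rows] = (p[src_rows] - Y_b) / max(len(src_rows), 1)
            ce_s = cross_entropy(p[src_rows], Y_b) if len(src_rows) else 0.0
            ce_t = 0.0
            tgt_rows = np.nonzero(~is_src & keep[np.maximum(idx - n_s, 0)])[0]
            if alpha > 0 and len(tgt_rows):
                Y_pb = Y_pseudo[idx[tgt_rows] - n_s]
                ce_t = cross_entropy(p[tgt_rows], Y_pb)
                grad_logits[tgt_rows] = alpha * (p[tgt_rows] - Y_pb) / len(tgt_rows)
            grad_z = bundle.C_multi.backward(grad_logits)

            # centroids on the current batch (full data when full-batch)
            act = active_all[idx]
            cent = centroid_alignment_loss(z[act], labels_all[idx[act]], domains[idx[act]], K)
            if config.centroid_weight > 0:
                g_cent = np.zeros_like(z)
                g_cent[act] = centroid_alignment_grad(
                    z[act], labels_all[idx[act]], domains[idx[act]], K
                )
                grad_z = grad_z + config.centroid_weight * g_cent

            grad_cat = bundle.G.backward(grad_z)
            offset = 0
            for o in range(bundle.n_modalities):
                width = 512
                bundle.F[o].backward(grad_cat[:, offset : offset + width])
                offset += width
            opt.step()
            _zero(*all_nets)
            ce_s_sum += ce_s
            ce_t_sum += ce_t
            cent_sum += cent
            n_batches += 1

        ce_s, ce_t, cent = ce_s_sum / n_batches, ce_t_sum / n_batches, cent_sum / n_batches
        _record(history, 4, t, "ssl_source_ce", ce_s)
        _record(history, 4, t, "ssl_target_ce", ce_t)
        _record(history, 4, t, "alpha", alpha)
        _record(history, 4, t, "centroid", cent)
        _record(history, 4, t, "ssl_total", ce_s + alpha * ce_t + config.centroid_weight * cent)
    return history


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def fit(
    source: MultiOmicsDataset,
    target: MultiOmicsDataset,
    config: Optional[TrainConfig] = None,
) -> tuple[ModelBundle, History]:
    """Run phases 1-4 (honoring ablation switches) and return the trained
    bundle plus the per-epoch loss history."""
    config = config or TrainConfig()
    if source.labels is None:
        raise ValueError("source dataset must be labeled")
    if source.n_modalities != target.n_modalities:
        raise ValueError("source and target disagree on modality count")
    for ms, mt in zip(source.matrices, target.matrices):
        if ms.feature_ids != mt.feature_ids:
            raise ValueError(
                f"modality {ms.modality!r}: source/target feature spaces differ"
            )
    _require_clean(source, "source")
    _require_clean(target, "target")
    bundle = build_bundle(source.feature_dims, source.n_classes, seed=config.seed)
    history: History = []
    history += phase1_pretrain(bundle, source, config)
    history += phase2_single_omics_da(bundle, source, target, config)
    history += phase3_multi_omics_da(bundle, source, target, config)
    history += phase4_semi_supervised(bundle, source, target, config)
    return bundle, history


def predict(bundle: ModelBundle, dataset: MultiOmicsDataset) -> EmbeddingResult:
    """Integrated latent + class posteriors for any dataset (inference mode)."""
    latent = forward_integrated(bundle, dataset.arrays(), train=False)
    posteriors = classify(bundle.C_multi, latent, train=False)
    return EmbeddingResult(
        latent=latent,
        posteriors=posteriors,
        predicted_labels=np.argmax(posteriors, axis=1) + 1,
        sample_ids=dataset.sample_ids,
        domain=dataset.domain,
        class_names=dataset.class_names,
    )


def probe_domain_accuracy(latent: np.ndarray, domain_labels: np.ndarray, seed: int = 0) -> float:
    """5-fold cross-validated accuracy of a logistic-regression probe that
    tries to tell the domains apart from a latent representation.  Values
    near 0.5 mean the domains are mixed; near 1.0 means they are separable."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    return float(cross_val_score(clf, latent, domain_labels, cv=cv).mean())


def history_frame(history: History):
    """History as a tidy (phase, epoch, loss_name, value) DataFrame."""
    import pandas as pd

    return pd.DataFrame(history, columns=["phase", "epoch", "loss", "value"]).rename(
        columns={"loss": "loss_name"}
    )
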