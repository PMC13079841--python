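"""Network construction: extractors, classifier heads, domain discriminators.

Component architectures (all fully connected, two hidden layers, LeakyReLU,
batch-norm after each hidden layer):

* per-modality extractor  ``F^(o)``: m^(o) -> 1024 -> 512 (512-d latent)
* shared extractor        ``G``:     O*512 -> 512 -> 256 (256-d latent)
* classifier heads        ``C``:     latent -> 128 -> 64 -> K logits (softmax)
* domain discriminators   ``D``:     latent -> 256 -> 64 -> 2 logits (softmax)

The classifier is conceptually a single head; because it is attached both to
512-d single-omics latents and to the 256-d integrated latent, one head per
attachment point is instantiated (same 128/64/softmax architecture).  All
final predictions come from the head on the integrated latent (``C_multi``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import BatchNorm, Linear, Sequential, mlp, softmax

SINGLE_LATENT_DIM = 512
SHARED_LATENT_DIM = 256
EXTRACTOR_HIDDEN = [1024, 512]
SHARED_HIDDEN = [512, 256]
CLASSIFIER_HIDDEN = [128, 64]
DISCRIMINATOR_HIDDEN = [256, 64]


@dataclass
class MLPSpec:
    """Architecture record for one component (used for checkpoint manifests)."""

    input_dim: int
    hidden_widths: list[int]
    output_dim: int | None
    final: str = "linear"  # "linear" or "softmax" (softmax applied outside the net)
    negative_slope: float = 0.01
    use_batch_norm: bool = True

    def build(self, rng: np.random.Generator) -> Sequential:
        return mlp(self.input_dim, self.hidden_widths, self.output_dim, rng,
                   slope=self.negative_slope)


@dataclass
class ModelBundle:
    """All trained parametric maps plus their architecture manifest."""

    F: list[Sequential]
    G: Sequential
    C_single: list[Sequential]
    C_multi: Sequential
    D_single: list[Sequential]
    D_shared: Sequential
    specs: dict = field(default_factory=dict)
    feature_dims: list[int] = field(default_factory=list)
    n_classes: int = 0
    latent_dim: int = SHARED_LATENT_DIM

    @property
    def n_modalities(self) -> int:
        return len(self.F)


def build_bundle(
    feature_dims: list[int],
    n_classes: int,
    seed: int = 0,
    negative_slope: float = 0.01,
) -> ModelBundle:
    """Construct a freshly initialized bundle for ``O = len(feature_dims)``
    modalities and ``K = n_classes`` classes, seeded for reproducibility."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if any(m < 1 for m in feature_dims):
        raise ValueError("feature dims must be >= 1")
    rng = np.random.default_rng(seed)
    O = len(feature_dims)
    specs = {
        "F": [MLPSpec(m, EXTRACTOR_HIDDEN, None) for m in feature_dims],
        "G": MLPSpec(O * SINGLE_LATENT_DIM, SHARED_HIDDEN, None),
        "C_single": [
            MLPSpec(SINGLE_LATENT_DIM, CLASSIFIER_HIDDEN, n_classes, final="softmax")
            for _ in range(O)
        ],
        "C_multi": MLPSpec(SHARED_LATENT_DIM, CLASSIFIER_HIDDEN, n_classes, final="softmax"),
        "D_single": [
            MLPSpec(SINGLE_LATENT_DIM, DISCRIMINATOR_HIDDEN, 2, final="softmax")
            for _ in range(O)
        ],
        "D_shared": MLPSpec(SHARED_LATENT_DIM, DISCRIMINATOR_HIDDEN, 2, final="softmax"),
    }
    for group in specs.values():
        for s in group if isinstance(group, list) else [group]:
            s.negative_slope = negative_slope
    bundle = ModelBundle(
        F=[s.build(rng) for s in specs["F"]],
        G=specs["G"].build(rng),
        C_single=[s.build(rng) for s in specs["C_single"]],
        C_multi=specs["C_multi"].build(rng),
        D_single=[s.build(rng) for s in specs["D_single"]],
        D_shared=specs["D_shared"].build(rng),
        specs=specs,
        feature_dims=list(feature_dims),
        n_classes=n_classes,
    )
    return bundle


def forward_single(bundle: ModelBundle, o: int, X: np.ndarray, train: bool = False) -> np.ndarray:
    """Per-modality latent ``F^(o)(X)`` (n x 512)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != bundle.feature_dims[o]:
        raise ValueError(
            f"modality {o}: expected {bundle.feature_dims[o]} features, got {X.shape[1]}"
        )
    return bundle.F[o].forward(X, train=train)

def concat_single(bundle: ModelBundle, X_list: list[np.ndarray], train: bool = False) -> np.ndarray:
    ns = {np.asarray(X).shape[0] for X in X_list}
    if len(ns) != 1:
        raise ValueError(f"modalities disagree on sample count: {sorted(ns)}")
    return np.concatenate(
        [forward_single(bundle, o, X, train=train) for o, X in enumerate(X_list)], axis=1
    )


def forward_integrated(bundle: ModelBundle, X_list: list[np.ndarray], train: bool = False) -> np.ndarray:
    """Integrated latent ``G(concat_o F^(o)(X^(o)))`` (n x 256)."""
    return bundle.G.forward(concat_single(bundle, X_list, train=train), train=train)


def classify(head: Sequential, latent: np.ndarray, train: bool = False) -> np.ndarray:
    """Row-stochastic class posteriors from a classifier head."""
    return softmax(head.forward(np.asarray(latent, dtype=float), train=train))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _components(bundle: ModelBundle) -> list[tuple[str, Sequential]]:
    out = []
    for o, net in enumerate(bundle.F):
        out.append((f"F{o}", net))
    out.append(("G", bundle.G))
    for o, net in enumerate(bundle.C_single):
        out.append((f"Cs{o}", net))
    out.append(("Cm", bundle.C_multi))
    for o, net in enumerate(bundle.D_single):
        out.append((f"Ds{o}", net))
    out.append(("Dsh", bundle.D_shared))
    return out


def _state_arrays(net: Sequential) -> list[np.ndarray]:
    arrs = []
    for layer in net.layers:
        if isinstance(layer, Linear):
            arrs += [layer.W.value, layer.b.value]
        elif isinstance(layer, BatchNorm):
            arrs += [layer.gamma.value, layer.beta.value, layer.running_mean, layer.running_var]
    return arrs


def save_bundle(bundle: ModelBundle, path: str) -> None:
    """Serialize parameters + architecture manifest to one ``.npz`` file."""
    arrays = {}
    for name, net in _components(bundle):
        for i, arr in enumerate(_state_arrays(net)):
            arrays[f"{name}.{i}"] = arr
    manifest = json.dumps(
        {"feature_dims": bundle.feature_dims, "n_classes": bundle.n_classes}
    )
    np.savez(path, __manifest__=np.array(manifest), **arrays)


def load_bundle(path: str) -> ModelBundle:
    """Rebuild a bundle from a checkpoint, validating the manifest."""
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["__manifest__"]))
        bundle = build_bundle(manifest["feature_dims"], manifest["n_classes"], seed=0)
        for name, net in _components(bundle):
            arrs = _state_arrays(net)
            for i, arr in enumerate(arrs):
                stored = data[f"{name}.{i}"]
                if stored.shape != arr.shape:
                    raise ValueError(f"checkpoint {name}.{i} shape mismatch")
                arr[...] = stored
    return bundle
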