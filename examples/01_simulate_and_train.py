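"""Simulate a two-modality source/target pair with a planted batch shift,
train the four-phase model, and transfer labels to the target cohort.

Run:  python examples/01_simulate_and_train.py
"""

from modamix import SimSpec, TrainConfig, fit, generate, predict
from modamix.evaluate import accuracy, evaluate_target

spec = SimSpec(
    n_source=300, n_target=300, n_classes=3, n_modalities=2,
    n_features=(200, 200), class_separation=6.0, batch_shift=12.0,
    batch_scale=0.0, noise_sd=1.0, seed=1,
)
source, target, truth = generate(spec)
print(f"source: {source.n_samples} samples x {source.feature_dims} features, "
      f"K={source.n_classes}; target unlabeled: {target.n_samples} samples")

bundle, history = fit(source, target, TrainConfig.reduced(seed=1))
result = predict(bundle, target)

acc = accuracy(result.predicted_labels, truth)
sil = evaluate_target(result, K=3, mode="pred").silhouette
print(f"target accuracy vs planted truth: {acc:.4f}")
print(f"silhouette of predicted classes in the integrated latent: {sil:.3f}")
print("-> labels transferred across the batch shift; classes form compact,"
      " separated clusters in the shared 256-d latent space.")
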