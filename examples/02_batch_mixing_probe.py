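"""Audit batch-effect removal with a domain probe.

A logistic-regression probe is retrained from scratch on the integrated
latent to tell the two cohorts apart: ~1.0 means the batch effect dominates,
~0.5 means the cohorts are mixed.  The probe is measured after pre-training
(phase 1) and again after the adversarial alignment phases (2-3).

Run:  python examples/02_batch_mixing_probe.py
"""

import numpy as np

from modamix import TrainConfig, make_fixture, probe_domain_accuracy
from modamix.networks import build_bundle, forward_integrated
from modamix.trainer import (
    phase1_pretrain,
    phase2_single_omics_da,
    phase3_multi_omics_da,
)

fx = make_fixture("easy", seed=1)
source, target = fx["source"], fx["target"]
cfg = TrainConfig.reduced(seed=1)
bundle = build_bundle(source.feature_dims, source.n_classes, seed=cfg.seed)
domains = np.r_[np.ones(source.n_samples), 2 * np.ones(target.n_samples)]


def integrated_probe():
    Z = np.vstack([
        forward_integrated(bundle, source.arrays()),
        forward_integrated(bundle, target.arrays()),
    ])
    return probe_domain_accuracy(Z, domains, seed=0)


phase1_pretrain(bundle, source, cfg)
p1 = integrated_probe()
phase2_single_omics_da(bundle, source, target, cfg)
phase3_multi_omics_da(bundle, source, target, cfg)
p3 = integrated_probe()

print(f"probe accuracy after pre-training:          {p1:.3f}")
print(f"probe accuracy after adversarial alignment: {p3:.3f}")
print("-> near 1.0 before alignment (the planted shift dominates the latent),"
      " near 0.5 after (a fresh probe can barely tell the cohorts apart).")
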