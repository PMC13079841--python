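import numpy as np
import pytest

from modamix import MultiOmicsDataset, OmicsMatrix, SimSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_pair():
    """A very small but learnable source/target pair for fast trainer tests."""
    spec = SimSpec(
        n_source=60, n_target=60, n_classes=2, n_modalities=2, n_features=(30, 30),
        latent_signal_dim=5, class_separation=6.0, batch_shift=4.0, batch_scale=0.0,
        noise_sd=0.5, seed=11,
    )
    return generate(spec)


@pytest.fixture
def small_matrix():
    return OmicsMatrix(
        values=np.arange(12, dtype=float).reshape(4, 3),
        sample_ids=["s1", "s2", "s3", "s4"],
        feature_ids=["g1", "g2", "g3"],
        modality="rna",
        domain="source",
    )


def make_dataset(values_list, labels=None, domain="source", class_names=None):
    n = values_list[0].shape[0]
    sample_ids = [f"{domain[0]}{i}" for i in range(n)]
    mats = [
        OmicsMatrix(
            values=v,
            sample_ids=sample_ids,
            feature_ids=[f"m{o}_f{j}" for j in range(v.shape[1])],
            modality=f"m{o}",
            domain=domain,
        )
        for o, v in enumerate(values_list)
    ]
    return MultiOmicsDataset(mats, domain=domain, labels=labels, class_names=class_names)
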