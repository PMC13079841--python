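"""Seeded generator of paired source/target multi-omics datasets.

The generative model is linear-Gaussian for analytical transparency: each
class ``k`` has a mean ``mu_k`` in a low-dimensional signal space (means are
mutually orthogonal with pairwise distance ``class_separation``; the
within-class spread in signal space is the unit ball, so separation is in
units of within-class standard deviations).  A per-modality random linear
map ``A^(o)`` — shared across domains, which is what gives the two cohorts a
common feature space — lifts signal vectors to feature space.  Batch effects
are planted per domain as an additive shift of magnitude ``batch_shift``
along a random per-modality direction plus a per-feature multiplicative
distortion of spread ``batch_scale``; independent Gaussian measurement noise
is added last.

The returned target dataset never carries labels; the ground truth is
returned separately so that evaluation code cannot accidentally leak it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_data import SOURCE, TARGET, MultiOmicsDataset, OmicsMatrix


@dataclass
class SimSpec:
    """Study conditions for one simulated source/target pair."""

    n_source: int = 300
    n_target: int = 300
    n_classes: int = 3
    n_modalities: int = 2
    n_features: tuple[int, ...] = (200, 200)
    latent_signal_dim: int = 10
    class_separation: float = 6.0
    batch_shift: float = 3.0
    batch_scale: float = 0.1
    noise_sd: float = 1.0
    class_proportions_source: Optional[tuple[float, ...]] = None
    class_proportions_target: Optional[tuple[float, ...]] = None
    shift_in_signal_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_features) != self.n_modalities:
            raise ValueError("n_features must list one width per modality")
        if min(self.n_source, self.n_target, self.n_classes, self.n_modalities) < 1:
            raise ValueError("counts must be >= 1")
        if self.latent_signal_dim < self.n_classes:
            raise ValueError("latent_signal_dim must be >= n_classes")
        for props in (self.class_proportions_source, self.class_proportions_target):
            if props is not None:
                if len(props) != self.n_classes or abs(sum(props) - 1.0) > 1e-8:
                    raise ValueError("class proportions must be length K and sum to 1")


def _deterministic_labels(n: int, props: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n samples to classes, then shuffled."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    labels = np.repeat(np.arange(1, len(props) + 1), counts)
    rng.shuffle(labels)
    return labels


def generate(spec: SimSpec) -> tuple[MultiOmicsDataset, MultiOmicsDataset, np.ndarray]:
    """Draw (source, target, target_truth) under ``spec``."""
    rng = np.random.default_rng(spec.seed)
    K, O, d = spec.n_classes, spec.n_modalities, spec.latent_signal_dim

    # orthonormal class directions scaled so all pairwise mean distances equal
    # class_separation
    Q, _ = np.linalg.qr(rng.normal(size=(d, K)))
    mu = Q.T * (spec.class_separation / np.sqrt(2.0))  # K x d

    props_s = np.asarray(spec.class_proportions_source or [1.0 / K] * K)
    props_t = np.asarray(spec.class_proportions_target or props_s)
    y_s = _deterministic_labels(spec.n_source, props_s, rng)
    y_t = _deterministic_labels(spec.n_target, props_t, rng)

    A = [rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, m)) for m in spec.n_features]
    shift_dir = {}
    scale = {}
    for o in range(O):
        for dom in (SOURCE, TARGET):
            # a random feature-space direction is almost orthogonal to the
            # class-signal image; shift_in_signal_frac plants that fraction of
            # the offset inside the signal subspace so the batch effect
            # actually collides with class-discriminative directions
            u = rng.normal(size=spec.n_features[o])
            u /= np.linalg.norm(u)
            v_img = rng.normal(size=d) @ A[o]
            v_img /= np.linalg.norm(v_img)
            w = spec.shift_in_signal_frac
            direction = np.sqrt(max(1.0 - w**2, 0.0)) * u + w * v_img
            shift_dir[o, dom] = direction / np.linalg.norm(direction)
            scale[o, dom] = 1.0 + spec.batch_scale * rng.normal(size=spec.n_features[o])

    def make_domain(y: np.ndarray, dom: str, tag: str) -> list[OmicsMatrix]:
        n = len(y)
        signal = mu[y - 1] + rng.normal(size=(n, d))
        mats = []
        for o in range(O):
            x = signal @ A[o]
            x = x * scale[o, dom] + spec.batch_shift * shift_dir[o, dom]
            x = x + spec.noise_sd * rng.normal(size=x.shape)
            mats.append(
                OmicsMatrix(
                    values=x,
                    sample_ids=[f"{tag}{i + 1}" for i in range(n)],
                    feature_ids=[f"mod{o + 1}_f{j + 1}" for j in range(spec.n_features[o])],
                    modality=f"mod{o + 1}",
                    domain=dom,
                )
            )
        return mats

    class_names = [f"class_{k}" for k in range(1, K + 1)]
    source = MultiOmicsDataset(
        make_domain(y_s, SOURCE, "S"), domain=SOURCE, labels=y_s, class_names=class_names
    )
    target = MultiOmicsDataset(
        make_domain(y_t, TARGET, "T"), domain=TARGET, labels=None, class_names=class_names
    )
    return source, target, y_t


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def _meth_toy() -> dict:
    """Beta-valued methylation toy with a planted missingness pattern.

    10 CpGs x (5 source + 5 target) samples.  cg_drop_1 and cg_drop_2 are
    missing in 3 of the 10 pooled samples (30% > 20% -> excluded);
    cg_keep_edge is missing in exactly 2 of 10 (20%, retained); every other
    CpG is complete.  cg_keep_edge's observed values are chosen so the pooled
    median used for imputation is 0.4.
    """
    rng = np.random.default_rng(7)
    cpgs = [f"cg_{i:03d}" for i in range(7)] + ["cg_keep_edge", "cg_drop_1", "cg_drop_2"]
    n_s, n_t = 5, 5
    vals = rng.uniform(0.05, 0.95, size=(n_s + n_t, len(cpgs)))
    mask = np.zeros_like(vals, dtype=bool)
    j_edge, j_d1, j_d2 = 7, 8, 9
    mask[[0, 5], j_edge] = True                 # 2/10 missing  -> kept
    mask[[1, 4, 8], j_d1] = True                # 3/10 missing  -> dropped
    mask[[0, 2, 9], j_d2] = True                # 3/10 missing  -> dropped
    observed_edge = [0.2, 0.3, 0.4, 0.4, 0.5, 0.6, 0.35, 0.45]
    vals[~mask[:, j_edge], j_edge] = observed_edge
    vals[mask] = np.nan

    def part(rows: slice, dom: str, tag: str) -> OmicsMatrix:
        return OmicsMatrix(
            values=vals[rows],
            sample_ids=[f"{tag}{i + 1}" for i in range(5)],
            feature_ids=list(cpgs),
            modality="meth",
            domain=dom,
            missing_mask=mask[rows],
        )

    return {
        "source": part(slice(0, 5), SOURCE, "MS"),
        "target": part(slice(5, 10), TARGET, "MT"),
        "dropped_cpgs": ["cg_drop_1", "cg_drop_2"],
        "edge_cpg": "cg_keep_edge",
        "edge_imputed_value": 0.4,
    }


def _atac_toy() -> dict:
    """Three genes and six peaks with hand-computable overlap sums.

    Coordinates are 0-based half-open.  Genes: gA=[100,200), gB=[300,400),
    gC=[350,500) (gB and gC overlap).  Peaks: p1 inside gA; p2 spans the
    gA/gB gap only; p3 inside both gB and gC; p4 inside gC only; p5 beyond
    all genes; p6 straddles gA's start.
    """
    from .preprocess import GeneAnnotation, PeakSet

    genes = [
        GeneAnnotation("gA", "chr1", 100, 200, "+"),
        GeneAnnotation("gB", "chr1", 300, 400, "+"),
        GeneAnnotation("gC", "chr1", 350, 500, "-"),
    ]
    peak_ids = ["p1", "p2", "p3", "p4", "p5", "p6"]
    chroms = ["chr1"] * 6
    starts = [120, 210, 360, 420, 600, 90]
    ends = [160, 290, 395, 480, 650, 110]
    counts = np.array(
        [  # samples x peaks
            [5, 1, 2, 3, 7, 1],
            [0, 2, 4, 1, 0, 2],
            [3, 3, 0, 0, 1, 0],
            [1, 0, 6, 2, 2, 4],
        ],
        dtype=float,
    )
    sample_ids = [f"A{i + 1}" for i in range(4)]
    peaks = PeakSet(peak_ids, chroms, starts, ends, counts, sample_ids)
    # hand-computed: gA <- p1 + p6; gB <- p3; gC <- p3 + p4
    expected = np.stack(
        [counts[:, 0] + counts[:, 5], counts[:, 2], counts[:, 2] + counts[:, 3]], axis=1
    )
    return {"peaks": peaks, "genes": genes, "expected_activity": expected}


def make_fixture(name: str, seed: int = 0) -> dict:
    """Named study fixtures.

    ``easy``     — K=3, O=2, m=(200,200), n=300/300, strong class separation
                   with a moderate planted batch shift; the full pipeline with
                   reduced epochs recovers target labels.
    ``hard``     — batch shift much larger than class separation (the regime
                   where adversarial alignment is load-bearing), at a smaller
                   problem size.
    ``meth_toy`` — beta-valued matrices with planted missing cells.
    ``atac_toy`` — 3-gene annotation + 6 peaks with hand-computable overlaps.
    """
    if name == "easy":
        spec = SimSpec(
            n_source=300, n_target=300, n_classes=3, n_modalities=2,
            n_features=(200, 200), latent_signal_dim=10,
            class_separation=6.0, batch_shift=12.0, batch_scale=0.0,
            noise_sd=1.0, seed=seed,
        )
        source, target, truth = generate(spec)
        return {"spec": spec, "source": source, "target": target, "truth": truth}
    if name == "hard":
        spec = SimSpec(
            n_source=200, n_target=200, n_classes=3, n_modalities=2,
            n_features=(100, 100), latent_signal_dim=10,
            class_separation=3.0, batch_shift=12.0, batch_scale=0.0,
            noise_sd=1.0, shift_in_signal_frac=0.7, seed=seed,
        )
        source, target, truth = generate(spec)
        return {"spec": spec, "source": source, "target": target, "truth": truth}
    if name == "meth_toy":
        return _meth_toy()
    if name == "atac_toy":
        return _atac_toy()
    raise ValueError(f"unknown fixture {name!r}")
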