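"""Single-cell style preprocessing: low-expression filtering, library-size
normalization with log1p, highly-variable-gene selection, and gene-activity
scores from accessibility peaks over gene bodies.

Run:  python examples/03_preprocess_expression_atac.py
"""

import numpy as np

from modamix.core_data import OmicsMatrix
from modamix.preprocess import (
    filter_low_expression,
    gene_activity_scores,
    normalize_log,
    select_hvg,
)
from modamix.synthetic import make_fixture

rng = np.random.default_rng(0)

# toy count matrices: 120 cells x 100 genes per cohort, shared gene space
genes = [f"g{j}" for j in range(100)]
counts_s = rng.poisson(rng.uniform(0.1, 8.0, size=100), size=(120, 100)).astype(float)
counts_t = rng.poisson(rng.uniform(0.1, 8.0, size=100), size=(90, 100)).astype(float)
src = OmicsMatrix(counts_s, [f"S{i}" for i in range(120)], genes, "rna", "source")
tgt = OmicsMatrix(counts_t, [f"T{i}" for i in range(90)], genes, "rna", "target")

src = filter_low_expression(src, min_cells=30)
tgt = tgt.subset_features(src.feature_ids)
print(f"genes expressed in >= 30 cells: {src.n_features} of 100")

src = normalize_log(src, target_sum=1e4)
tgt = normalize_log(tgt, target_sum=1e4)
src_hvg, tgt_hvg = select_hvg(src, tgt, n_genes=20)
print(f"top dispersion-ranked genes kept in both cohorts: {src_hvg.n_features}"
      f" (identical order: {src_hvg.feature_ids == tgt_hvg.feature_ids})")

# accessibility: sum peak counts over gene bodies (>=1 bp overlap)
fx = make_fixture("atac_toy")
activity = gene_activity_scores(fx["peaks"], fx["genes"])
print("gene-activity table (4 samples x 3 genes):")
print(activity.values)
print("-> each column sums the counts of the peaks overlapping that gene's"
      " body; peaks between genes contribute nothing.")
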