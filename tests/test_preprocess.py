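"""Feature-engineering operators: boundary rules, hand-computed toys, oracles."""

import numpy as np
import pytest

from modamix.core_data import OmicsMatrix
from modamix.preprocess import (
    CpGClusterModel,
    GeneAnnotation,
    PeakSet,
    apply_cpg_clusters,
    cluster_cpgs,
    filter_impute_cpgs,
    filter_low_expression,
    gene_activity_scores,
    match_genes_to_cpg_features,
    normalize_log,
    read_gene_annotation_bed,
    select_hvg,
)
from modamix.synthetic import make_fixture


def expr_matrix(values, domain="source"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        values,
        [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        "rna",
        domain,
    )


class TestFilterLowExpression:
    def test_boundary_at_min_cells(self, rng):
        # gene 0 nonzero in exactly 30 cells (kept), gene 1 in 29 (removed)
        vals = np.zeros((100, 2))
        vals[:30, 0] = 1.0
        vals[:29, 1] = 1.0
        out = filter_low_expression(expr_matrix(vals), min_cells=30)
        assert out.feature_ids == ["g0"]

    def test_zero_threshold_is_identity(self):
        mat = expr_matrix([[0.0, 1.0], [2.0, 0.0]])
        out = filter_low_expression(mat, min_cells=0)
        assert out.feature_ids == mat.feature_ids

    def test_all_removed_errors(self):
        with pytest.raises(ValueError):
            filter_low_expression(expr_matrix([[1.0], [0.0]]), min_cells=5)


class TestNormalizeLog:
    def test_hand_computed_single_sample(self):
        out = normalize_log(expr_matrix([[1.0, 3.0]]), target_sum=4.0)
        np.testing.assert_allclose(out.values[0], [np.log(2.0), np.log(4.0)], atol=1e-12)

    def test_equal_rows_map_identically(self):
        out = normalize_log(expr_matrix([[2.0, 4.0], [2.0, 4.0]]), target_sum=10.0)
        np.testing.assert_allclose(out.values[0], out.values[1])

    def test_inverse_identity_row_sums(self, rng):
        vals = rng.integers(0, 50, size=(6, 10)).astype(float)
        vals[:, 0] += 1  # no all-zero rows
        out = normalize_log(expr_matrix(vals), target_sum=1e4)
        np.testing.assert_allclose(np.expm1(out.values).sum(axis=1), 1e4, atol=1e-6)

    def test_all_zero_sample_named(self):
        with pytest.raises(ValueError, match="c1"):
            normalize_log(expr_matrix([[1.0, 2.0], [0.0, 0.0]]))


class TestSelectHVG:
    def test_identity_when_n_genes_large(self):
        src = expr_matrix(np.log1p(np.random.default_rng(0).uniform(0, 5, (20, 8))))
        tgt = expr_matrix(np.log1p(np.random.default_rng(1).uniform(0, 5, (10, 8))), "target")
        a, b = select_hvg(src, tgt, n_genes=100)
        assert a.feature_ids == src.feature_ids

    def test_planted_high_dispersion_genes_recovered(self, rng):
        n, m = 200, 205
        # base genes: a spread of means so dispersion bins are well populated
        lam = rng.uniform(2.0, 10.0, size=m)
        base = rng.poisson(lam, size=(n, m)).astype(float)
        # plant 5 overdispersed genes (gamma-Poisson, ~4x Poisson dispersion)
        # with distinct in-range means so each sits in a different mean bin
        for j, scale in enumerate([3.0, 3.5, 4.0, 4.5, 5.0]):
            base[:, j] = rng.poisson(rng.gamma(2.0, scale, size=n)).astype(float)
        log_vals = np.log1p(base)
        src = expr_matrix(log_vals)
        tgt = expr_matrix(log_vals[:50], "target")
        a, b = select_hvg(src, tgt, n_genes=5)
        assert set(a.feature_ids) == {f"g{j}" for j in range(5)}
        assert a.feature_ids == b.feature_ids

    def test_agrees_with_scanpy_seurat_flavor(self, rng):
        scanpy = pytest.importorskip("scanpy")
        import anndata

        counts = rng.poisson(3.0, size=(150, 60)).astype(float) + rng.gamma(
            1.0, 2.0, size=(150, 60)
        )
        log_vals = np.log1p(counts)
        adata = anndata.AnnData(log_vals.copy())
        scanpy.pp.highly_variable_genes(adata, n_top_genes=15, flavor="seurat", n_bins=20)
        expected = set(np.nonzero(adata.var["highly_variable"].to_numpy())[0])
        src = expr_matrix(log_vals)
        a, _ = select_hvg(src, expr_matrix(log_vals[:20], "target"), n_genes=15)
        got = {int(f[1:]) for f in a.feature_ids}
        # criteria agree up to tie handling at the cutoff
        assert len(got & expected) >= 13


class TestGeneActivity:
    def overlap_oracle(self, peaks, genes):
        """Explicit O(peaks x genes) double loop."""
        out = np.zeros((len(peaks.sample_ids), len(genes)))
        for j, g in enumerate(genes):
            for q in range(len(peaks.peak_ids)):
                if peaks.chroms[q] != g.chrom:
                    continue
                lo = max(peaks.starts[q], g.start)
                hi = min(peaks.ends[q], g.end)
                if hi - lo >= 1:
                    out[:, j] += peaks.counts[:, q]
        return out

    def test_atac_toy_matches_hand_computed_table(self):
        fx = make_fixture("atac_toy")
        mat = gene_activity_scores(fx["peaks"], fx["genes"])
        np.testing.assert_allclose(mat.values, fx["expected_activity"])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(5):
            n_p, n_g, n_s = 40, 12, 6
            starts = rng.integers(0, 5000, size=n_p)
            peaks = PeakSet(
                [f"p{i}" for i in range(n_p)],
                [f"chr{c}" for c in rng.integers(1, 3, size=n_p)],
                starts.tolist(),
                (starts + rng.integers(50, 400, size=n_p)).tolist(),
                rng.integers(0, 9, size=(n_s, n_p)).astype(float),
                [f"s{i}" for i in range(n_s)],
            )
            gs = rng.integers(0, 5000, size=n_g)
            genes = [
                GeneAnnotation(f"g{i}", f"chr{rng.integers(1, 3)}", int(gs[i]),
                               int(gs[i] + rng.integers(100, 1500)))
                for i in range(n_g)
            ]
            mat = gene_activity_scores(peaks, genes)
            np.testing.assert_allclose(mat.values, self.overlap_oracle(peaks, genes))

    def test_missing_gene_id_listed(self):
        fx = make_fixture("atac_toy")
        with pytest.raises(ValueError, match="gX"):
            gene_activity_scores(fx["peaks"], fx["genes"], gene_ids=["gA", "gX"])

    def test_isolated_peak_contributes_nothing(self):
        fx = make_fixture("atac_toy")
        mat = gene_activity_scores(fx["peaks"], fx["genes"])
        # p5 ([600,650)) overlaps no gene: dropping it changes nothing
        peaks = fx["peaks"]
        keep = [i for i, pid in enumerate(peaks.peak_ids) if pid != "p5"]
        trimmed = PeakSet(
            [peaks.peak_ids[i] for i in keep],
            [peaks.chroms[i] for i in keep],
            [peaks.starts[i] for i in keep],
            [peaks.ends[i] for i in keep],
            peaks.counts[:, keep],
            peaks.sample_ids,
        )
        np.testing.assert_allclose(gene_activity_scores(trimmed, fx["genes"]).values, mat.values)


class TestFilterImputeCpgs:
    def test_meth_toy_drop_and_keep_rules(self):
        fx = make_fixture("meth_toy")
        src, tgt = filter_impute_cpgs(fx["source"], fx["target"], max_missing_frac=0.2)
        assert not any(c in src.feature_ids for c in fx["dropped_cpgs"])
        assert fx["edge_cpg"] in src.feature_ids  # exactly 20% missing is retained
        assert not src.has_missing and not tgt.has_missing

    def test_median_imputation_value(self):
        fx = make_fixture("meth_toy")
        src, tgt = filter_impute_cpgs(fx["source"], fx["target"])
        j = src.feature_ids.index(fx["edge_cpg"])
        imputed_rows = np.nonzero(fx["source"].missing_mask[:, fx["source"].feature_ids.index(fx["edge_cpg"])])[0]
        for i in imputed_rows:
            assert src.values[i, j] == pytest.approx(fx["edge_imputed_value"], abs=1e-12)

    def test_observed_values_untouched(self):
        fx = make_fixture("meth_toy")
        src, _ = filter_impute_cpgs(fx["source"], fx["target"])
        orig = fx["source"]
        for f in src.feature_ids:
            jo = orig.feature_ids.index(f)
            jn = src.feature_ids.index(f)
            obs = ~orig.missing_mask[:, jo]
            np.testing.assert_array_equal(src.values[obs, jn], orig.values[obs, jo])

    def test_simple_median_by_hand(self):
        vals_s = np.array([[0.2], [0.4], [np.nan]])
        mask_s = np.isnan(vals_s)
        src = OmicsMatrix(vals_s, ["a", "b", "c"], ["cg1"], "meth", "source", mask_s)
        tgt = OmicsMatrix(np.array([[0.6]]), ["t1"], ["cg1"], "meth", "target")
        out_s, _ = filter_impute_cpgs(src, tgt, max_missing_frac=0.5)
        assert out_s.values[2, 0] == pytest.approx(0.4)  # median of {0.2, 0.4, 0.6}

    def test_no_common_cpg_errors(self):
        a = OmicsMatrix(np.ones((2, 1)), ["a", "b"], ["cg1"], "meth", "source")
        b = OmicsMatrix(np.ones((2, 1)), ["c", "d"], ["cg2"], "meth", "target")
        with pytest.raises(ValueError):
            filter_impute_cpgs(a, b)


class TestCpGClustering:
    def beta_matrix(self, values, domain="source"):
        values = np.asarray(values, dtype=float)
        return OmicsMatrix(
            values,
            [f"s{i}" for i in range(values.shape[0])],
            [f"cg{j}" for j in range(values.shape[1])],
            "meth",
            domain,
        )

    def test_singleton_clusters_are_identity(self, rng):
        mat = self.beta_matrix(rng.uniform(size=(5, 4)))
        model = cluster_cpgs(mat, n_clusters=4, seed=0)
        out = apply_cpg_clusters(model, mat)
        assert out.n_features == 4
        # each cluster feature equals one original CpG column
        for c in range(4):
            members = [cg for cg, a in model.cluster_assignment.items() if a == c]
            assert len(members) == 1
            j = mat.feature_ids.index(members[0])
            np.testing.assert_allclose(out.values[:, c], mat.values[:, j])

    def test_planted_groups_recovered(self, rng):
        # two CpG groups with very different profiles across samples
        lo = rng.uniform(0.0, 0.05, size=(6, 10))
        hi = rng.uniform(0.95, 1.0, size=(6, 10))
        mat = self.beta_matrix(np.hstack([lo, hi]))
        model = cluster_cpgs(mat, n_clusters=2, seed=0)
        groups = [model.cluster_assignment[f"cg{j}"] for j in range(20)]
        assert len(set(groups[:10])) == 1 and len(set(groups[10:])) == 1
        assert groups[0] != groups[10]

    def test_deterministic_under_seed(self, rng):
        mat = self.beta_matrix(rng.uniform(size=(8, 12)))
        m1 = cluster_cpgs(mat, n_clusters=3, seed=42)
        m2 = cluster_cpgs(mat, n_clusters=3, seed=42)
        assert m1.cluster_assignment == m2.cluster_assignment

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_cpgs(self.beta_matrix(rng.uniform(size=(4, 3))), n_clusters=5, seed=0)

    def test_cluster_median_by_hand(self):
        mat = self.beta_matrix(np.array([[0.1, 0.3, 0.9]]))
        model = CpGClusterModel(1, {"cg0": 0, "cg1": 0, "cg2": 0}, 0)
        out = apply_cpg_clusters(model, mat)
        assert out.values[0, 0] == pytest.approx(0.3)
        assert out.feature_ids == ["cluster_0001"]


class TestPromoterMatching:
    def _expr(self, genes, n=30, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.log1p(rng.uniform(0, 5, size=(n, len(genes))))
        return OmicsMatrix(vals, [f"s{i}" for i in range(n)], genes, "rna", "source")

    def test_strand_aware_window(self):
        anno = [
            GeneAnnotation("plus", "chr1", 10000, 12000, "+"),
            GeneAnnotation("minus", "chr1", 30000, 32000, "-"),
        ]
        model = CpGClusterModel(2, {"cgA": 0, "cgB": 1}, 0)
        # cgA 500 bp upstream of plus-strand TSS (10000); cgB 500 bp upstream
        # of minus-strand TSS (31999), i.e. at 32499
        pos = {"cgA": ("chr1", 9500), "cgB": ("chr1", 32499)}
        out = match_genes_to_cpg_features(
            self._expr(["plus", "minus"]), model, anno, pos, promoter_window=2000, n_genes=10
        )
        assert set(out.feature_ids) == {"plus", "minus"}

    def test_distal_cpg_not_matched(self):
        anno = [GeneAnnotation("g", "chr1", 10000, 12000, "+")]
        model = CpGClusterModel(1, {"cg": 0}, 0)
        pos = {"cg": ("chr1", 22000)}  # 10 kb downstream
        with pytest.raises(ValueError):
            match_genes_to_cpg_features(self._expr(["g"]), model, anno, pos)

    def test_huge_window_matches_same_chromosome(self):
        anno = [
            GeneAnnotation("near", "chr1", 5_000_000, 5_001_000, "+"),
            GeneAnnotation("other", "chr2", 100, 1100, "+"),
        ]
        model = CpGClusterModel(1, {"cg": 0}, 0)
        pos = {"cg": ("chr1", 10)}
        out = match_genes_to_cpg_features(
            self._expr(["near", "other"]), model, anno, pos,
            promoter_window=10_000_000, n_genes=10,
        )
        assert out.feature_ids == ["near"]


def test_bed_reader_round_trip(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t100\t200\tgA\t0\t+\nchr2\t300\t500\tgB\t0\t-\n")
    genes = read_gene_annotation_bed(str(bed))
    assert [g.gene_id for g in genes] == ["gA", "gB"]
    assert genes[1].strand == "-" and genes[1].tss == 499


def test_paired_outputs_share_feature_order(rng):
    counts = rng.poisson(4.0, size=(40, 30)).astype(float)
    src = normalize_log(expr_matrix(counts + 1))
    tgt = normalize_log(expr_matrix(rng.poisson(4.0, size=(25, 30)).astype(float) + 1, "target"))
    a, b = select_hvg(src, tgt, n_genes=10)
    assert a.feature_ids == b.feature_ids
    fx = make_fixture("meth_toy")
    s, t = filter_impute_cpgs(fx["source"], fx["target"])
    assert s.feature_ids == t.feature_ids
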