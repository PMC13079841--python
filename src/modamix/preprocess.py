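"""Feature engineering for expression, chromatin accessibility and methylation.

Every paired operation returns source/target matrices whose ``feature_ids``
agree in content and order — the cross-domain feature correspondence the
model requires.

Conventions: genomic coordinates are 0-based half-open; interval overlap
means a non-empty intersection (>= 1 bp); methylation beta values live in
[0, 1] where observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_data import OmicsMatrix


@dataclass
class GeneAnnotation:
    """Gene body interval (0-based half-open) with strand for promoter logic."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if not self.chrom:
            raise ValueError(f"{self.gene_id}: empty chrom")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PeakSet:
    """Accessibility peaks with per-sample counts (samples x peaks)."""

    peak_ids: list[str]
    chroms: list[str]
    starts: list[int]
    ends: list[int]
    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        p = len(self.peak_ids)
        if not (len(self.chroms) == len(self.starts) == len(self.ends) == p):
            raise ValueError("peak coordinate arrays disagree in length")
        if self.counts.shape != (len(self.sample_ids), p):
            raise ValueError("counts must be samples x peaks")
        if (self.counts < 0).any():
            raise ValueError("peak counts must be >= 0")
        for pid, s, e in zip(self.peak_ids, self.starts, self.ends):
            if s >= e:
                raise ValueError(f"peak {pid}: start must be < end")


@dataclass
class CpGClusterModel:
    """K-means grouping of CpGs (fitted in sample-space) into feature clusters."""

    n_clusters: int
    cluster_assignment: dict[str, int]
    random_seed: int

    def __post_init__(self) -> None:
        used = set(self.cluster_assignment.values())
        if used and (min(used) < 0 or max(used) >= self.n_clusters):
            raise ValueError("cluster indices out of range")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.cluster_assignment)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def filter_low_expression(expr: OmicsMatrix, min_cells: int = 30) -> OmicsMatrix:
    """Drop genes with nonzero counts in fewer than ``min_cells`` samples."""
    if (expr.values[~expr.missing_mask] < 0).any():
        raise ValueError("expression counts must be nonnegative")
    n_expressed = (expr.values > 0).sum(axis=0)
    keep = [f for f, c in zip(expr.feature_ids, n_expressed) if c >= min_cells]
    if not keep:
        raise ValueError(f"all genes expressed in fewer than {min_cells} samples")
    return expr.subset_features(keep)


def normalize_log(expr: OmicsMatrix, target_sum: float = 1e4) -> OmicsMatrix:
    """Scale each sample to ``target_sum`` total counts, then log1p."""
    totals = expr.values.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[expr.sample_ids[i] for i in zero[:5]]}")
    scaled = expr.values * (target_sum / totals)[:, None]
    return OmicsMatrix(
        values=np.log1p(scaled),
        sample_ids=expr.sample_ids,
        feature_ids=expr.feature_ids,
        modality=expr.modality,
        domain=expr.domain,
    )


def _normalized_dispersion(log_values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned dispersion z-scores on log-normalized data.

    Dispersion = var/mean of the de-logged values; genes are binned into
    ``n_bins`` equal-width mean bins and the dispersion is z-scored within
    its bin (bins with a single member or zero spread get spread 1)."""
    x = np.expm1(log_values)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros_like(mean)
    raw = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    # log-scale dispersion and mean stabilize the binning (zero-dispersion
    # genes rank last)
    disp = np.where(raw > 0, np.log(np.maximum(raw, 1e-300)), -np.inf)
    log_mean = np.log1p(mean)
    bins = pd.cut(log_mean, bins=n_bins, labels=False, duplicates="drop")
    bins = np.nan_to_num(np.asarray(bins, dtype=float), nan=0.0).astype(int)
    z = np.empty_like(raw)
    for b in np.unique(bins):
        sel = bins == b
        finite = sel & np.isfinite(disp)
        if finite.sum() > 1:
            mu = disp[finite].mean()
            sd = disp[finite].std(ddof=1)
            z[sel] = (disp[sel] - mu) / (sd if sd > 0 else 1.0)
        else:
            # a bin with a single informative gene carries no spread estimate;
            # normalize it to its own dispersion (z = 1)
            z[sel] = np.where(np.isfinite(disp[sel]), 1.0, -np.inf)
    return np.where(np.isfinite(z), z, -np.inf)


def select_hvg(
    expr_source: OmicsMatrix, expr_target: OmicsMatrix, n_genes: int = 3000
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Rank shared genes by normalized dispersion on the source and keep the
    top ``min(n_genes, available)`` in both matrices, same order."""
    shared = [f for f in expr_source.feature_ids if f in set(expr_target.feature_ids)]
    if len(shared) < 1:
        raise ValueError("no shared genes between source and target")
    src = expr_source.subset_features(shared)
    z = _normalized_dispersion(src.values)
    order = np.argsort(-z, kind="stable")[: min(n_genes, len(shared))]
    keep = [shared[i] for i in sorted(order)]  # preserve original gene order
    return expr_source.subset_features(keep), expr_target.subset_features(keep)


# ---------------------------------------------------------------------------
# chromatin accessibility
# ---------------------------------------------------------------------------

def gene_activity_scores(
    peaks: PeakSet,
    genes: Sequence[GeneAnnotation],
    gene_ids: Optional[Sequence[str]] = None,
    modality: str = "atac_activity",
    domain: str = "source",
) -> OmicsMatrix:
    """Per-gene accessibility scores: the sum of counts of all peaks whose
    interval overlaps the gene body by at least one base.  Genes with no
    overlapping peak get all-zero columns."""
    by_id = {g.gene_id: g for g in genes}
    if gene_ids is None:
        gene_ids = [g.gene_id for g in genes]
    missing = [g for g in gene_ids if g not in by_id]
    if missing:
        raise ValueError(f"gene_id(s) absent from annotation: {missing}")
    starts = np.asarray(peaks.starts)
    ends = np.asarray(peaks.ends)
    chroms = np.asarray(peaks.chroms, dtype=object)
    scores = np.zeros((len(peaks.sample_ids), len(gene_ids)))
    for j, gid in enumerate(gene_ids):
        g = by_id[gid]
        hit = (chroms == g.chrom) & (starts < g.end) & (ends > g.start)
        if hit.any():
            scores[:, j] = peaks.counts[:, hit].sum(axis=1)
    return OmicsMatrix(
        values=scores,
        sample_ids=list(peaks.sample_ids),
        feature_ids=list(gene_ids),
        modality=modality,
        domain=domain,
    )


# ---------------------------------------------------------------------------
# DNA methylation
# ---------------------------------------------------------------------------

def filter_impute_cpgs(
    meth_source: OmicsMatrix,
    meth_target: OmicsMatrix,
    max_missing_frac: float = 0.2,
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Keep CpGs shared by both domains whose pooled missing fraction does not
    exceed ``max_missing_frac``; impute remaining missing cells with the
    pooled per-CpG median of observed values.  Observed values never change.
    """
    shared = [f for f in meth_source.feature_ids if f in set(meth_target.feature_ids)]
    if not shared:
        raise ValueError("no CpG sites common to source and target")
    src = meth_source.subset_features(shared)
    tgt = meth_target.subset_features(shared)
    pooled = np.vstack([src.values, tgt.values])
    pooled_mask = np.vstack([src.missing_mask, tgt.missing_mask])
    frac = pooled_mask.mean(axis=0)
    keep_idx = np.nonzero(frac <= max_missing_frac)[0]
    if keep_idx.size == 0:
        raise ValueError("every shared CpG exceeds the missingness threshold")
    keep = [shared[i] for i in keep_idx]
    src = src.subset_features(keep)
    tgt = tgt.subset_features(keep)
    obs = np.vstack([src.values, tgt.values]).copy()
    obs[np.vstack([src.missing_mask, tgt.missing_mask])] = np.nan
    med = np.nanmedian(obs, axis=0)

    def impute(mat: OmicsMatrix) -> OmicsMatrix:
        vals = mat.values.copy()
        rows, cols = np.nonzero(mat.missing_mask)
        vals[rows, cols] = med[cols]
        return OmicsMatrix(
            values=vals,
            sample_ids=mat.sample_ids,
            feature_ids=mat.feature_ids,
            modality=mat.modality,
            domain=mat.domain,
        )

    return impute(src), impute(tgt)


def cluster_cpgs(meth_source: OmicsMatrix, n_clusters: int = 3000, seed: int = 0) -> CpGClusterModel:
    """Group CpGs into feature clusters by K-means in source-sample space
    (each CpG is a point whose coordinates are its beta values across the
    source samples; k-means++ init, 10 restarts, fixed seed)."""
    if meth_source.has_missing:
        raise ValueError("cluster_cpgs requires an imputed, missing-free matrix")
    n_cpgs = meth_source.n_features
    if n_clusters > n_cpgs:
        raise ValueError(f"n_clusters={n_clusters} exceeds the {n_cpgs} CpGs available")
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed)
    assign = km.fit_predict(meth_source.values.T)
    return CpGClusterModel(
        n_clusters=n_clusters,
        cluster_assignment=dict(zip(meth_source.feature_ids, (int(a) for a in assign))),
        random_seed=seed,
    )


def apply_cpg_clusters(model: CpGClusterModel, meth: OmicsMatrix) -> OmicsMatrix:
    """Collapse CpGs to cluster features: per-sample median beta over the
    CpGs assigned to each cluster.  Features are named cluster_0001..."""
    missing = [c for c in model.cpg_ids if c not in set(meth.feature_ids)]
    if missing:
        raise ValueError(f"matrix lacks CpG(s) in the cluster model: {missing[:5]}")
    col = {f: i for i, f in enumerate(meth.feature_ids)}
    width = max(4, len(str(model.n_clusters)))
    out = np.zeros((meth.n_samples, model.n_clusters))
    members: list[list[int]] = [[] for _ in range(model.n_clusters)]
    for cpg, c in model.cluster_assignment.items():
        members[c].append(col[cpg])
    for c, idx in enumerate(members):
        if idx:
            out[:, c] = np.median(meth.values[:, idx], axis=1)
    return OmicsMatrix(
        values=out,
        sample_ids=meth.sample_ids,
        feature_ids=[f"cluster_{c + 1:0{width}d}" for c in range(model.n_clusters)],
        modality=meth.modality,
        domain=meth.domain,
    )


def match_genes_to_cpg_features(
    expr: OmicsMatrix,
    model: CpGClusterModel,
    gene_annotation: Sequence[GeneAnnotation],
    cpg_positions: dict[str, tuple[str, int]],
    promoter_window: int = 2000,
    n_genes: int = 3000,
) -> OmicsMatrix:
    """Keep genes with >= 1 retained CpG in their promoter (strand-aware
    window from ``promoter_window`` bp upstream of the TSS through the TSS),
    ranked by normalized dispersion and truncated to ``n_genes``."""
    by_id = {g.gene_id: g for g in gene_annotation}
    missing = [g for g in expr.feature_ids if g not in by_id]
    if missing:
        raise ValueError(f"annotation lacks gene(s): {missing[:5]}")
    unplaced = [c for c in model.cpg_ids if c not in cpg_positions]
    if unplaced:
        raise ValueError(f"positions lack CpG(s): {unplaced[:5]}")
    by_chrom: dict[str, list[int]] = {}
    for c in model.cpg_ids:
        chrom, pos = cpg_positions[c]
        by_chrom.setdefault(chrom, []).append(int(pos))
    matched = []
    for gid in expr.feature_ids:
        g = by_id[gid]
        if g.strand == "+":
            lo, hi = g.tss - promoter_window, g.tss
        else:
            lo, hi = g.tss, g.tss + promoter_window
        if any(lo <= p <= hi for p in by_chrom.get(g.chrom, ())):
            matched.append(gid)
    if not matched:
        raise ValueError("no gene has a retained CpG within its promoter window")
    sub = expr.subset_features(matched)
    z = _normalized_dispersion(sub.values)
    order = np.argsort(-z, kind="stable")[: min(n_genes, len(matched))]
    keep = [matched[i] for i in sorted(order)]
    return expr.subset_features(keep)


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

def read_gene_annotation_bed(path: str) -> list[GeneAnnotation]:
    """BED6-like reader: chrom, start, end, gene_id, score (ignored), strand."""
    genes = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: BED line needs >= 4 columns: {line!r}")
            strand = parts[5] if len(parts) >= 6 else "+"
            genes.append(GeneAnnotation(parts[3], parts[0], int(parts[1]), int(parts[2]), strand))
    return genes


def read_cpg_positions(path: str) -> dict[str, tuple[str, int]]:
    """Two-column (cpg_id, chrom:pos) table."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        cpg, loc = str(row.iloc[0]), str(row.iloc[1])
        chrom, pos = loc.rsplit(":", 1)
        out[cpg] = (chrom, int(pos))
    return out


def read_peaks_bed(path: str, sample_ids: list[str] | None = None) -> PeakSet:
    """BED3+ with per-sample count columns after the coordinates (an optional
    4th name column is used for peak IDs when present and non-numeric)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    chroms = df.iloc[:, 0].tolist()
    starts = df.iloc[:, 1].astype(int).tolist()
    ends = df.iloc[:, 2].astype(int).tolist()
    first_extra = 3
    peak_ids = [f"peak_{i + 1}" for i in range(len(df))]
    if df.shape[1] > 3:
        try:
            float(df.iloc[0, 3])
        except ValueError:
            peak_ids = df.iloc[:, 3].tolist()
            first_extra = 4
    counts = df.iloc[:, first_extra:].astype(float).to_numpy().T
    if sample_ids is None:
        sample_ids = [f"sample_{i + 1}" for i in range(counts.shape[0])]
    return PeakSet(peak_ids, chroms, starts, ends, counts, sample_ids)
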