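"""Single-cell multiome core: QC, normalization, HVGs, scoring, DE.

RNA counts are library-normalized (counts per 10k, log1p); ATAC counts
use log TF-IDF.  Differential expression is a per-gene Mann-Whitney
rank-sum test with Benjamini-Hochberg correction, excluding genes
detected in fewer than 1% of cells of either compared group.  The gene
identity score quantifies how confined a gene's expression is to its
wild-type-defined primary germ layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .genomic import CellTable, CountMatrix
from .stats import bh_adjust, rank_sum_test

__all__ = [
    "NormalizedMatrix",
    "qc_filter",
    "normalize_rna",
    "tfidf",
    "select_hvgs",
    "signature_score",
    "wilcoxon_de",
    "primary_germ_layers",
    "gene_identity_score",
]

LOG2FC_EPS = 1e-9


@dataclass
class NormalizedMatrix:
    """Features × cells matrix of library-normalized, log-transformed values."""

    features: list[str]
    cells: list[str]
    X: sparse.csr_matrix

    def __post_init__(self):
        self.X = sparse.csr_matrix(self.X, dtype=float)
        if self.X.shape != (len(self.features), len(self.cells)):
            raise ValueError("matrix shape inconsistent with feature/cell lists")
        if self.X.nnz:
            if not np.all(np.isfinite(self.X.data)):
                raise ValueError("non-finite normalized values")
            if self.X.data.min() < 0:
                raise ValueError("normalized values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def feature_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.features)}
        missing = [g for g in ids if g not in lookup]
        if missing:
            raise KeyError(f"features not found: {missing[:5]}")
        return np.array([lookup[g] for g in ids], dtype=int)

    def row(self, feature: str) -> np.ndarray:
        i = self.feature_index([feature])[0]
        return np.asarray(self.X[i].todense()).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        idx = np.flatnonzero(mask)
        return NormalizedMatrix(
            self.features, [self.cells[i] for i in idx], self.X[:, idx]
        )


def qc_filter(
    rna: CountMatrix,
    cells: CellTable,
    mito_genes: set[str],
    min_counts: int = 300,
    min_genes: int = 200,
    max_mito_frac: float = 0.20,
) -> tuple[CountMatrix, CellTable]:
    """Discard low-quality cells.

    A cell is kept when it has at least ``min_counts`` total counts, at
    least ``min_genes`` detected genes, and at most ``max_mito_frac`` of
    its counts from mitochondrial genes — all three thresholds inclusive
    (the discard rules are strict "less than" / "more than").
    """
    unknown = mito_genes - set(rna.features)
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {sorted(unknown)[:5]}")
    totals = rna.cell_totals()
    n_genes = rna.genes_per_cell()
    if mito_genes:
        mito_idx = rna.feature_index(sorted(mito_genes))
        mito_counts = np.asarray(rna.X[mito_idx].sum(axis=0)).ravel()
    else:
        mito_counts = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    keep = (totals >= min_counts) & (n_genes >= min_genes) & (mito_frac <= max_mito_frac)
    if not keep.any():
        raise ValueError(
            "QC removed every cell; review min_counts/min_genes/max_mito_frac "
            "against the library depth"
        )
    return rna.subset_cells(keep), cells.subset(keep)


def normalize_rna(rna: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """Counts-per-``scale`` normalization followed by natural-log1p.

    value = ln(1 + count / cell_total × scale).  Cells with zero total
    counts are rejected (they should have been removed by QC).
    """
    totals = rna.cell_totals()
    if np.any(totals == 0):
        raise ValueError("all-zero cell encountered; run qc_filter first")
    X = rna.X.tocsc(copy=True).astype(float)
    X.data = X.data * (scale / np.repeat(totals, np.diff(X.indptr)))
    X.data = np.log1p(X.data)
    return NormalizedMatrix(list(rna.features), list(rna.cells), X.tocsr())


def tfidf(atac: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """Log TF-IDF normalization of an ATAC count matrix.

    value = ln(1 + (c_ij / colsum_j) × (n_cells / ncells_i) × scale)
    where ``ncells_i`` is the number of cells in which peak *i* is
    detected.  Peaks open in zero cells get an all-zero row (warning).
    """
    totals = atac.cell_totals()
    if np.any(totals == 0):
        raise ValueError("all-zero cell encountered; run qc_filter first")
    n_cells = atac.shape[1]
    row_cells = np.asarray((atac.X > 0).sum(axis=1)).ravel().astype(float)
    n_empty = int((row_cells == 0).sum())
    if n_empty:
        warnings.warn(f"{n_empty} peaks open in zero cells; their rows stay 0")
    idf = np.divide(
        n_cells, row_cells, out=np.zeros_like(row_cells), where=row_cells > 0
    )
    coo = atac.X.tocoo().astype(float)
    tf = coo.data / totals[coo.col]
    vals = np.log1p(tf * idf[coo.row] * scale)
    X = sparse.csr_matrix((vals, (coo.row, coo.col)), shape=atac.shape)
    return NormalizedMatrix(list(atac.features), list(atac.cells), X)


def select_hvgs(norm: NormalizedMatrix, n: int = 2000) -> list[str]:
    """Top-``n`` genes by trend-standardized variance.

    Genes are rank-binned by mean expression and the expected variance
    of each bin is its median gene variance — a trend robust to the
    minority of genuinely variable genes.  Each gene's values are then
    standardized with its own mean but the sd expected from the trend,
    clipped at ``sqrt(n_cells)``, and the variance of the clipped
    standardized values ranks the genes (variance-stabilizing HVG
    selection).  Standardizing against the trend, rather than each
    gene's own sd, is what lets overdispersed genes stand out.  Ties
    break deterministically by gene id; constant genes score zero and
    can never outrank a varying gene.
    """
    if n > len(norm.features):
        raise ValueError("n exceeds number of genes")
    X = norm.X
    n_cells = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(mean_sq - mean**2, 0.0) * n_cells / max(n_cells - 1, 1)

    usable = np.flatnonzero((mean > 0) & (var > 0))
    scores = np.zeros(len(norm.features))
    if usable.size:
        n_trend_bins = min(20, max(1, usable.size // 10))
        order = usable[np.argsort(mean[usable], kind="mergesort")]
        bin_of = {}
        for rank, i in enumerate(order):
            bin_of[i] = rank * n_trend_bins // usable.size
        trend = {
            b: np.median([var[i] for i in usable if bin_of[i] == b])
            for b in range(n_trend_bins)
        }
        clip = np.sqrt(n_cells)
        for i in usable:
            sd_trend = np.sqrt(trend[bin_of[i]])
            z = (np.asarray(X[i].todense()).ravel() - mean[i]) / sd_trend
            z = np.clip(z, -clip, clip)
            scores[i] = z.var(ddof=1)
    order = sorted(
        range(len(norm.features)), key=lambda i: (-scores[i], norm.features[i])
    )
    return [norm.features[i] for i in order[:n]]


def signature_score(
    norm: NormalizedMatrix,
    gene_set: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature score against expression-matched controls.

    Genes are binned by mean expression; for each bin containing
    signature genes, ``n_ctrl`` control genes are sampled (seeded) from
    the bin excluding the signature itself.  The score is the cell's
    mean expression over the signature minus its mean over the pooled
    controls, so a random gene set scores ~0.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(norm.features)
    if missing:
        raise ValueError(f"signature genes absent from matrix: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    mean_expr = np.asarray(norm.X.mean(axis=1)).ravel()
    # with few genes, shrink the binning so every signature bin can
    # still supply controls from outside the signature
    n_bins = min(n_bins, max(1, len(mean_expr) // 4))
    order = np.argsort(mean_expr, kind="mergesort")
    bin_of = np.empty(len(mean_expr), dtype=int)
    bin_of[order] = np.arange(len(mean_expr)) * n_bins // len(mean_expr)

    sig_idx = norm.feature_index(list(gene_set))
    sig_set = set(sig_idx.tolist())
    ctrl: set[int] = set()
    for b in sorted(set(bin_of[sig_idx])):
        pool = [i for i in np.flatnonzero(bin_of == b) if i not in sig_set]
        if not pool:
            continue
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        raise ValueError("no control genes available outside the signature")
    sig_mean = np.asarray(norm.X[sig_idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(norm.X[sorted(ctrl)].mean(axis=0)).ravel()
    return sig_mean - ctrl_mean


def wilcoxon_de(
    norm: NormalizedMatrix,
    cells: CellTable,
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_expr_frac: float = 0.01,
) -> pd.DataFrame:
    """Rank-sum differential expression between two cell groups.

    ``group_a`` / ``group_b`` are boolean masks over cells.  Genes
    detected (count > 0) in at least ``min_expr_frac`` of cells of BOTH
    groups are tested; p-values are BH-adjusted across tested genes.
    log2fc compares mean expm1-backtransformed expression with a small
    pseudocount.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if group_a.sum() < 3 or group_b.sum() < 3:
        raise ValueError("each group needs at least 3 cells")
    Xa = norm.X[:, np.flatnonzero(group_a)]
    Xb = norm.X[:, np.flatnonzero(group_b)]
    frac_a = np.asarray((Xa > 0).sum(axis=1)).ravel() / Xa.shape[1]
    frac_b = np.asarray((Xb > 0).sum(axis=1)).ravel() / Xb.shape[1]
    testable = np.flatnonzero((frac_a >= min_expr_frac) & (frac_b >= min_expr_frac))

    records = []
    for i in testable:
        a = np.asarray(Xa[i].todense()).ravel()
        b = np.asarray(Xb[i].todense()).ravel()
        u, p = rank_sum_test(a, b)
        mean_a = np.expm1(a).mean()
        mean_b = np.expm1(b).mean()
        log2fc = np.log2((mean_a + LOG2FC_EPS) / (mean_b + LOG2FC_EPS))
        records.append((norm.features[i], log2fc, u, p))
    df = pd.DataFrame(records, columns=["gene", "log2fc", "statistic", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def primary_germ_layers(
    wt_norm: NormalizedMatrix,
    wt_cells: CellTable,
    genes: Sequence[str],
    layers: Sequence[str] | None = None,
) -> dict[str, str]:
    """Primary germ layer per gene: argmax of mean wild-type expression.

    Ties break by layer name order for determinism.
    """
    if layers is None:
        layers = sorted(set(wt_cells.germ_layer))
    idx = wt_norm.feature_index(list(genes))
    layer_means = {}
    for layer in layers:
        mask = wt_cells.germ_layer == layer
        if not mask.any():
            continue
        sub = wt_norm.X[np.ix_(idx, np.flatnonzero(mask))]
        layer_means[layer] = np.asarray(sub.mean(axis=1)).ravel()
    if not layer_means:
        raise ValueError("no cells in any requested layer")
    names = sorted(layer_means)
    M = np.vstack([layer_means[l] for l in names])
    best = np.argmax(M, axis=0)
    return {g: names[b] for g, b in zip(genes, best)}


def gene_identity_score(
    norm: NormalizedMatrix,
    cells: CellTable,
    genes: Sequence[str],
    primary: Mapping[str, str],
) -> pd.DataFrame:
    """Fraction of a gene's expressing cells found in its primary layer.

    ``primary`` maps each gene to its wild-type-defined germ layer; the
    score is computed over the cells in ``norm``/``cells`` (typically one
    genotype at a time).  Genes expressed in zero cells get a missing
    score.  The score is invariant to cell order and expression scale.
    """
    idx = norm.feature_index(list(genes))
    layer = cells.germ_layer
    records = []
    for g, i in zip(genes, idx):
        expr = np.asarray(norm.X[i].todense()).ravel() > 0
        n_expr = int(expr.sum())
        if n_expr == 0:
            records.append((g, primary[g], np.nan, 0))
            continue
        n_in_layer = int((expr & (layer == primary[g])).sum())
        records.append((g, primary[g], n_in_layer / n_expr, n_expr))
    return pd.DataFrame(
        records, columns=["gene", "primary_layer", "score", "n_expressing"]
    )
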