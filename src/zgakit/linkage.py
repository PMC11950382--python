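"""Peak-to-gene linkage and promoter/enhancer analyses.

A peak is linked to a gene when its accessibility correlates with the
gene's expression across single cells more strongly than expected for
background peaks of comparable GC content, mean accessibility and
width.  For each candidate (gene, peak) pair within a genomic window of
the TSS, the observed Pearson r is z-scored against the correlations of
the same gene with the candidate's nearest background peaks in
standardized (gc, accessibility, log-width) space, and a one-sided
upper-tail normal p-value is attached — positive regulation is the
alternative of interest.

Downstream, each gene gets at most one promoter peak (most accessible
peak overlapping TSS ± 500 bp) and one enhancer peak (best significant
link within ±20 kb, excluding the promoter window), and the
expression-accessibility coupling of the two element classes is
compared per cell, per germ layer, and across knockdown fold changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.neighbors import NearestNeighbors

from .genomic import CellTable, GeneRecord, PeakSet
from .multiome import NormalizedMatrix
from .stats import rank_sum_test, spearman

__all__ = [
    "link_peaks",
    "assign_promoter",
    "assign_enhancer",
    "build_cre_map",
    "per_cell_correlation",
    "compare_correlations",
    "per_layer_correlation",
    "kd_logfc_correlation",
]


def _background_features(peaks: PeakSet, atac: NormalizedMatrix) -> np.ndarray:
    """Standardized (gc, mean accessibility, log width) per peak."""
    idx = atac.feature_index(peaks.ids())
    mean_acc = np.asarray(atac.X[idx].mean(axis=1)).ravel()
    gc = np.array([iv.gc if iv.gc is not None else 0.5 for iv in peaks])
    logw = np.log([iv.width for iv in peaks])
    F = np.column_stack([gc, mean_acc, logw])
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    return (F - F.mean(axis=0)) / sd


def link_peaks(
    rna: NormalizedMatrix,
    atac: NormalizedMatrix,
    genes: list[GeneRecord],
    peaks: PeakSet,
    window: int = 20_000,
    n_background: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Correlate peak accessibility with gene expression, background-matched.

    Returns one row per candidate (gene, peak) pair — every peak whose
    interval lies within ``window`` bp of the gene's TSS — with columns
    ``gene, peak, r, z, p``.  ``p`` is one-sided (upper tail).  Pairs
    with constant expression or accessibility are skipped; a degenerate
    null (sd = 0) leaves ``z``/``p`` as NaN.  Background matching is a
    deterministic nearest-neighbour query, so ``seed`` is accepted only
    for interface uniformity.
    """
    if rna.cells != atac.cells:
        raise ValueError("RNA and ATAC matrices must share the same cells")
    if len(peaks) < n_background + 1:
        raise ValueError(
            f"need more than n_background={n_background} peaks, got {len(peaks)}"
        )
    n_cells = len(rna.cells)

    peak_idx = atac.feature_index(peaks.ids())
    A = np.asarray(atac.X[peak_idx].todense())
    A_sd = A.std(axis=1)
    A_ok = A_sd > 0
    Az = np.zeros_like(A)
    Az[A_ok] = (A[A_ok] - A[A_ok].mean(axis=1, keepdims=True)) / A_sd[A_ok, None]

    feats = _background_features(peaks, atac)
    nn = NearestNeighbors(n_neighbors=min(n_background + 1, len(peaks)))
    nn.fit(feats)
    neigh = nn.kneighbors(feats, return_distance=False)
    # drop self from each neighbour list
    bg = np.empty((len(peaks), neigh.shape[1] - 1), dtype=int)
    for i in range(len(peaks)):
        row = neigh[i][neigh[i] != i]
        bg[i] = row[: bg.shape[1]]

    records = []
    for g in genes:
        cand = [
            k
            for k, iv in enumerate(peaks)
            if (d := iv.distance_to_point(g.chrom, g.tss)) is not None and d < window
        ]
        if not cand:
            continue
        e = rna.row(g.gene_id)
        e_sd = e.std()
        if e_sd == 0:
            continue
        ez = (e - e.mean()) / e_sd
        r_all = Az @ ez / n_cells  # Pearson r of this gene with every peak
        for k in cand:
            if not A_ok[k]:
                continue
            null_r = r_all[bg[k]][A_ok[bg[k]]]
            r = float(r_all[k])
            mu, sd = float(null_r.mean()), float(null_r.std(ddof=1))
            if sd == 0:
                z = p = np.nan
            else:
                z = (r - mu) / sd
                p = float(sps.norm.sf(z))
            records.append((g.gene_id, peaks[k].id, r, z, p))
    df = pd.DataFrame(records, columns=["gene", "peak", "r", "z", "p"])
    return df.sort_values(["gene", "r"], ascending=[True, False]).reset_index(drop=True)


def assign_promoter(
    atac: NormalizedMatrix,
    gene: GeneRecord,
    peaks: PeakSet,
    flank: int = 500,
    cell_mask: np.ndarray | None = None,
) -> str | None:
    """Most accessible peak overlapping TSS ± ``flank``; None if absent.

    ``cell_mask`` restricts the accessibility average (typically to
    wild-type cells).  Ties break to the lexicographically smaller peak
    id.
    """
    lo, hi = gene.tss - flank, gene.tss + flank + 1  # inclusive +/- flank
    cands = [
        iv for iv in peaks
        if iv.chrom == gene.chrom and iv.start < hi and iv.end > lo
    ]
    if not cands:
        return None
    idx = atac.feature_index([iv.id for iv in cands])
    X = atac.X[idx]
    if cell_mask is not None:
        X = X[:, np.flatnonzero(np.asarray(cell_mask, dtype=bool))]
    means = np.asarray(X.mean(axis=1)).ravel()
    best = sorted(zip(-means, [iv.id for iv in cands]))[0][1]
    return best


def assign_enhancer(
    links: pd.DataFrame,
    gene: GeneRecord,
    peaks: PeakSet,
    window: int = 20_000,
    promoter_flank: int = 500,
    alpha: float = 0.05,
) -> str | None:
    """Best significant linked peak within ±``window`` of the TSS.

    Candidates must have a one-sided p below ``alpha`` and positive r,
    lie within the window, and not overlap the promoter region
    (TSS ± ``promoter_flank``).  The peak with maximal r wins; ties
    break to the smaller peak id.  A function of the link table only.
    """
    sub = links[(links["gene"] == gene.gene_id) & (links["p"] < alpha) & (links["r"] > 0)]
    if sub.empty:
        return None
    plo, phi = gene.tss - promoter_flank, gene.tss + promoter_flank + 1
    best_id, best_r = None, -np.inf
    for _, row in sub.iterrows():
        iv = peaks.get(row["peak"])
        d = iv.distance_to_point(gene.chrom, gene.tss)
        if d is None or d >= window:
            continue
        if iv.start < phi and iv.end > plo:  # promoter overlap → excluded
            continue
        if row["r"] > best_r or (row["r"] == best_r and row["peak"] < best_id):
            best_id, best_r = row["peak"], row["r"]
    return best_id


def build_cre_map(
    atac: NormalizedMatrix,
    genes: list[GeneRecord],
    peaks: PeakSet,
    links: pd.DataFrame,
    promoter_flank: int = 500,
    enhancer_window: int = 20_000,
    alpha: float = 0.05,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene promoter and enhancer peak assignment (cis-regulatory map).

    Genes lacking either element keep a missing entry and are excluded
    by the correlation analyses downstream.
    """
    rows = []
    for g in genes:
        prom = assign_promoter(atac, g, peaks, flank=promoter_flank, cell_mask=cell_mask)
        enh = assign_enhancer(
            links, g, peaks, window=enhancer_window,
            promoter_flank=promoter_flank, alpha=alpha,
        )
        rows.append((g.gene_id, prom, enh))
    return pd.DataFrame(rows, columns=["gene", "promoter_peak", "enhancer_peak"])


def per_cell_correlation(
    rna: NormalizedMatrix,
    atac: NormalizedMatrix,
    cre: pd.DataFrame,
    hvgs: list[str],
    which: str = "enhancer",
) -> np.ndarray:
    """Per-cell Spearman between expression and element accessibility.

    Uses the HVGs that have BOTH a promoter and an enhancer assigned, so
    the promoter and enhancer distributions are computed over the same
    gene set.  Requires at least 3 usable genes.
    """
    if which not in ("promoter", "enhancer"):
        raise ValueError("which must be 'promoter' or 'enhancer'")
    usable = cre.dropna(subset=["promoter_peak", "enhancer_peak"])
    usable = usable[usable["gene"].isin(hvgs)]
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} genes with both elements; need >= 3")
    g_idx = rna.feature_index(list(usable["gene"]))
    p_idx = atac.feature_index(list(usable[f"{which}_peak"]))
    E = np.asarray(rna.X[g_idx].todense())
    Acc = np.asarray(atac.X[p_idx].todense())
    n_cells = E.shape[1]
    out = np.empty(n_cells)
    for j in range(n_cells):
        out[j] = spearman(E[:, j], Acc[:, j])
    return out


def compare_correlations(rho_prom, rho_enh) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing the two per-cell distributions."""
    rho_prom = np.asarray(rho_prom, dtype=float)
    rho_enh = np.asarray(rho_enh, dtype=float)
    rho_prom = rho_prom[np.isfinite(rho_prom)]
    rho_enh = rho_enh[np.isfinite(rho_enh)]
    if len(rho_prom) < 3 or len(rho_enh) < 3:
        raise ValueError("each sample needs at least 3 finite values")
    return rank_sum_test(rho_prom, rho_enh)


def per_layer_correlation(
    rna: NormalizedMatrix,
    atac: NormalizedMatrix,
    cells: CellTable,
    cre: pd.DataFrame,
    genes: list[str],
    which: str = "enhancer",
) -> pd.Series:
    """Per-gene Spearman between per-layer mean expression and accessibility.

    Averages both modalities within each germ layer and correlates the
    two layer profiles per gene; degenerate (constant) profiles give NaN.
    """
    layers = sorted(set(cells.germ_layer))
    if len(layers) < 3:
        raise ValueError("need at least 3 germ layers")
    cre_idx = cre.set_index("gene")
    col = f"{which}_peak"
    out = {}
    masks = [np.flatnonzero(cells.germ_layer == l) for l in layers]
    for g in genes:
        if g not in cre_idx.index or pd.isna(cre_idx.loc[g, col]):
            out[g] = np.nan
            continue
        e = rna.row(g)
        a = atac.row(cre_idx.loc[g, col])
        e_prof = np.array([e[m].mean() for m in masks])
        a_prof = np.array([a[m].mean() for m in masks])
        out[g] = spearman(e_prof, a_prof)
    return pd.Series(out, name=f"rho_{which}")


def kd_logfc_correlation(
    de_gex: pd.DataFrame, de_element: pd.DataFrame
) -> tuple[float, float]:
    """Spearman between expression and element-accessibility fold changes.

    Both inputs need ``gene``, ``layer`` and ``log2fc`` columns (one row
    per gene per germ layer, knockdown vs wild type); pairs are pooled
    over gene × layer.
    """
    merged = de_gex.merge(
        de_element, on=["gene", "layer"], suffixes=("_gex", "_atac")
    ).dropna(subset=["log2fc_gex", "log2fc_atac"])
    if len(merged) < 3:
        raise ValueError("fewer than 3 matched (gene, layer) pairs")
    res = sps.spearmanr(merged["log2fc_gex"], merged["log2fc_atac"])
    return float(res.statistic), float(res.pvalue)
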