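"""Synthetic early-embryo multiome, CUT&Tag and RNAPII data.

The generator emulates the statistical structure the analyses assume,
with ground truth recorded for recovery tests:

* germ-layer-structured RNA counts whose expression is driven by the
  accessibility of a planted enhancer peak, while promoter peaks are
  uniformly open regardless of expression;
* per-cell-type mutually exclusive H3K27me3/H3K27ac assignments whose
  pooled pseudo-bulk creates ambivalent peaks;
* per-sample sequencing-depth and nuclei-count confounding with a
  lambda spike-in (depth-proportional only) and a total-H3 control
  (depth- and nuclei-proportional);
* strand-aware RNAPII-S5P tracks with a tunable promoter-proximal
  pausing ratio and a knockdown condition that raises it.

Every generator is deterministic given the config seed.  RNA counts are
negative-binomial (gamma-Poisson) with dispersion 0.3, a typical
droplet-overdispersion level; ATAC counts are Bernoulli-gated shifted
Poisson so "open" peaks carry at least one fragment.  The genome is a
single chromosome with one gene per fixed-width slot, which keeps every
peak of a gene inside its own linkage window and outside every
neighbour's.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse

from .genomic import (
    CellTable,
    CountMatrix,
    GeneRecord,
    GenomicInterval,
    PeakSet,
    SignalTrack,
)
from .cutntag import MarkLibrary

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_multiome",
    "simulate_mark_libraries",
    "simulate_rnapii_tracks",
    "mark_peak_sets",
]

GENE_SLOT = 50_000  # bp of genome per gene
NB_DISPERSION = 0.3
MITO_FRACTION = 0.05
ATAC_POISSON_MEAN = 1.5
ENHANCER_OPEN_IN_TYPE = 0.8
ENHANCER_OPEN_ELSEWHERE = 0.05
BASE_RNA_MEAN = 1.0
MITO_RNA_MEAN = 2.0

_LAYER_NAMES = ("mesoderm", "ectoderm", "endoderm", "yolk", "undifferentiated")


@dataclass
class SyntheticConfig:
    """Study conditions for all three generators."""

    n_cell_types: int = 4
    cells_per_type: int = 300
    n_genes: int = 100
    n_peaks_per_gene: int = 5
    genome_length_bp: int | None = None
    enhancer_effect: float = 2.0
    promoter_open_prob: float = 0.8
    mark_discordance_rate: float = 0.2
    depth_factors: tuple = (1.0, 1.0)
    nuclei_factors: tuple = (1.0, 1.0)
    pausing_ratio_wt: float = 2.0
    pausing_ratio_kd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.genome_length_bp is None:
            self.genome_length_bp = self.n_genes * GENE_SLOT
        for name in ("n_cell_types", "cells_per_type", "n_genes",
                     "n_peaks_per_gene", "genome_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        if self.enhancer_effect < 0:
            raise ValueError("enhancer_effect must be non-negative")
        for name in ("promoter_open_prob", "mark_discordance_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if len(self.depth_factors) != len(self.nuclei_factors):
            raise ValueError("depth_factors and nuclei_factors must align")
        if any(f <= 0 for f in self.depth_factors + self.nuclei_factors):
            raise ValueError("depth and nuclei factors must be positive")
        if self.pausing_ratio_wt <= 0 or self.pausing_ratio_kd <= 0:
            raise ValueError("pausing ratios must be positive")
        if self.n_peaks_per_gene < 2:
            raise ValueError("need at least promoter + enhancer per gene")

    @property
    def layers(self) -> list[str]:
        if self.n_cell_types <= len(_LAYER_NAMES):
            return list(_LAYER_NAMES[: self.n_cell_types])
        return [f"layer{i}" for i in range(self.n_cell_types)]


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    enhancer_of: dict = field(default_factory=dict)      # gene -> peak id
    mark_of: dict = field(default_factory=dict)          # (cell_type, peak) -> state
    marker_genes: dict = field(default_factory=dict)     # cell_type -> set of genes
    pausing_param: dict = field(default_factory=dict)    # (condition, gene) -> ratio

    def to_json(self, path) -> None:
        payload = {
            "enhancer_of": self.enhancer_of,
            "mark_of": {f"{ct}|{pk}": st for (ct, pk), st in self.mark_of.items()},
            "marker_genes": {k: sorted(v) for k, v in self.marker_genes.items()},
            "pausing_param": {f"{c}|{g}": v for (c, g), v in self.pausing_param.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_layout(cfg: SyntheticConfig) -> tuple[list[GeneRecord], PeakSet, dict]:
    """One gene per slot, alternating strand, with promoter/enhancer/noise peaks."""
    slot = cfg.genome_length_bp // cfg.n_genes
    if slot < 45_000:
        raise ValueError(
            "genome_length_bp gives < 45 kb per gene; peaks of neighbouring "
            "genes would enter each other's linkage windows"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    genes, intervals = [], []
    enhancer_of = {}
    body_len = 8000
    # noise-peak offsets relative to the TSS, clear of the promoter
    # (+/-500), the enhancer (-6 kb) and the slot boundary
    noise_offsets = [4000, -15000, 9000, -10000, 14000, -18000, 17000, 2000]
    for i in range(cfg.n_genes):
        gid = f"g{i:04d}"
        tss = i * slot + slot // 2
        strand = "+" if i % 2 == 0 else "-"
        body_end = tss + body_len if strand == "+" else tss - body_len
        genes.append(GeneRecord(gid, "chrS", tss, strand, body_end))
        intervals.append(
            GenomicInterval("chrS", tss - 200, tss + 200, id=f"{gid}_prom",
                            gc=float(rng.uniform(0.35, 0.65)))
        )
        enh = GenomicInterval("chrS", tss - 6200, tss - 5800, id=f"{gid}_enh",
                              gc=float(rng.uniform(0.35, 0.65)))
        intervals.append(enh)
        enhancer_of[gid] = enh.id
        for k in range(cfg.n_peaks_per_gene - 2):
            off = noise_offsets[k % len(noise_offsets)]
            intervals.append(
                GenomicInterval("chrS", tss + off - 200, tss + off + 200,
                                id=f"{gid}_bg{k}", gc=float(rng.uniform(0.35, 0.65)))
            )
    return genes, PeakSet(intervals), enhancer_of


def simulate_multiome(
    cfg: SyntheticConfig,
    genotype: str = "WT",
    n_leak_layers: int = 0,
    leak_rate: float = 0.0,
):
    """Simulate a paired RNA + ATAC single-cell experiment.

    Each gene is a marker of one cell type (round-robin assignment).
    Its promoter peak is open in every cell with probability
    ``promoter_open_prob`` independently of expression; its enhancer
    peak is open predominantly in the gene's cell type, and RNA counts
    are negative-binomial with mean ``BASE_RNA_MEAN × (1 +
    enhancer_effect)`` in cells whose enhancer copy is open.  Noise
    peaks have cell-type-independent accessibility.  A labelled 5% of
    genes are mitochondrial (flat expression, no peaks) so the QC filter
    is exercisable.

    ``n_leak_layers``/``leak_rate`` emulate a knockdown that de-confines
    marker expression: in each of ``n_leak_layers`` extra cell types,
    cells activate the gene with probability ``leak_rate`` regardless of
    enhancer state.

    Returns ``(rna, atac, cells, genes, peaks, truth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes, peaks, enhancer_of = _gene_layout(cfg)
    layers = cfg.layers
    n_cells = cfg.n_cell_types * cfg.cells_per_type
    cell_type = np.repeat(np.arange(cfg.n_cell_types), cfg.cells_per_type)
    cell_ids = [f"{genotype}_c{i:05d}" for i in range(n_cells)]

    truth = SyntheticTruth(enhancer_of=enhancer_of)
    gene_type = {g.gene_id: i % cfg.n_cell_types for i, g in enumerate(genes)}
    for t, layer in enumerate(layers):
        truth.marker_genes[layer] = {g for g, ty in gene_type.items() if ty == t}

    # extra layers a marker leaks into under the knockdown
    leak_into = {}
    for g in genes:
        others = [t for t in range(cfg.n_cell_types) if t != gene_type[g.gene_id]]
        chosen = rng.choice(others, size=min(n_leak_layers, len(others)), replace=False)
        leak_into[g.gene_id] = set(int(t) for t in chosen)

    # --- ATAC ---
    atac_rows = []
    enhancer_open = {}  # gene -> boolean per cell, reused to drive RNA
    for g in genes:
        gid = g.gene_id
        for iv in peaks:
            if not iv.id.startswith(gid + "_"):
                continue
            if iv.id.endswith("_prom"):
                p_open = np.full(n_cells, cfg.promoter_open_prob)
            elif iv.id.endswith("_enh"):
                p_open = np.where(
                    cell_type == gene_type[gid],
                    ENHANCER_OPEN_IN_TYPE,
                    ENHANCER_OPEN_ELSEWHERE,
                )
            else:
                p_open = np.full(n_cells, float(rng.uniform(0.1, 0.4)))
            open_ = rng.random(n_cells) < p_open
            counts = open_ * (1 + rng.poisson(ATAC_POISSON_MEAN, size=n_cells))
            if iv.id.endswith("_enh"):
                enhancer_open[gid] = open_
            atac_rows.append((iv.id, counts))
    atac_features = [pid for pid, _ in atac_rows]
    atac_X = sparse.csr_matrix(
        np.vstack([c for _, c in atac_rows]).astype(np.int64)
    )

    # --- RNA ---
    n_mito = max(1, int(round(MITO_FRACTION * cfg.n_genes)))
    rna_features = [g.gene_id for g in genes] + [f"mt:mito{j}" for j in range(n_mito)]
    mu = np.empty((len(rna_features), n_cells))
    for i, g in enumerate(genes):
        boost = enhancer_open[g.gene_id].astype(float)
        if n_leak_layers and leak_rate > 0:
            leak_mask = np.isin(cell_type, list(leak_into[g.gene_id]))
            leak_hit = leak_mask & (rng.random(n_cells) < leak_rate)
            boost = np.maximum(boost, leak_hit.astype(float))
        mu[i] = BASE_RNA_MEAN * (1.0 + cfg.enhancer_effect * boost)
    mu[len(genes):] = MITO_RNA_MEAN
    shape = 1.0 / NB_DISPERSION
    lam = rng.gamma(shape, mu * NB_DISPERSION)
    rna_X = sparse.csr_matrix(rng.poisson(lam).astype(np.int64))

    cells = CellTable(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "germ_layer": [layers[t] for t in cell_type],
                "genotype": genotype,
                "replicate": "r1",
            }
        )
    )
    rna = CountMatrix(rna_features, cell_ids, rna_X)
    atac = CountMatrix(atac_features, cell_ids, atac_X)
    return rna, atac, cells, genes, peaks, truth


# ---------------------------------------------------------------------------
# Dual-mark CUT&Tag libraries


MARK_PEAK_WIDTH = 600
MARK_PEAK_SPACING = 2000
MARK_SIGNAL_HEIGHT = 1.0
H3_SIGNAL_HEIGHT = 1.0
LAMBDA_BASE_READS = 10_000
TRACK_BIN = 10


def _mark_peaks(cfg: SyntheticConfig) -> PeakSet:
    n_peaks = 2 * cfg.n_genes
    intervals = [
        GenomicInterval(
            "chrS",
            1000 + i * MARK_PEAK_SPACING,
            1000 + i * MARK_PEAK_SPACING + MARK_PEAK_WIDTH,
            id=f"mp{i:04d}",
        )
        for i in range(n_peaks)
    ]
    if intervals[-1].end > cfg.genome_length_bp:
        raise ValueError("genome too short for the mark peak layout")
    return PeakSet(intervals)


def simulate_mark_libraries(cfg: SyntheticConfig):
    """Simulate pooled dual-mark CUT&Tag libraries with controls.

    Every peak carries exactly one of {me3, ac, none} per cell type.  A
    fraction ``mark_discordance_rate`` of peaks is discordant: cell
    types split between me3 and ac (at least one of each), so the pooled
    pseudo-bulk shows both marks there.  Concordant peaks carry the same
    state in every cell type.

    Per sample *s*, raw pooled coverage scales with ``depth_factors[s] ×
    nuclei_factors[s]``; lambda spike-in reads scale with depth only;
    the total-H3 control covers every peak for every cell type (each
    nucleus contributes H3 everywhere).  Tracks are expected (noise
    free) coverage, so normalization identities hold exactly.

    Returns ``(libraries, tracks_by_sample, peaks, truth)``.
    """
    if cfg.mark_discordance_rate > 0 and cfg.n_cell_types < 2:
        raise ValueError("mark discordance requires at least 2 cell types")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    peaks = _mark_peaks(cfg)
    layers = cfg.layers
    truth = SyntheticTruth()

    for iv in peaks:
        if rng.random() < cfg.mark_discordance_rate:
            # discordant: split cell types between the two marks
            n_me3 = int(rng.integers(1, cfg.n_cell_types))
            perm = rng.permutation(cfg.n_cell_types)
            for pos, t in enumerate(perm):
                truth.mark_of[(layers[t], iv.id)] = "me3" if pos < n_me3 else "ac"
        else:
            state = rng.choice(["me3", "ac", "none"], p=[0.4, 0.4, 0.2])
            for layer in layers:
                truth.mark_of[(layer, iv.id)] = str(state)

    n_bins = cfg.genome_length_bp // TRACK_BIN
    base = {}
    for mark in ("me3", "ac"):
        arr = np.zeros(n_bins)
        for iv in peaks:
            n_types = sum(
                truth.mark_of[(layer, iv.id)] == mark for layer in layers
            )
            if n_types:
                arr[iv.start // TRACK_BIN : iv.end // TRACK_BIN] += (
                    MARK_SIGNAL_HEIGHT * n_types
                )
        base[mark] = arr
    h3_base = np.zeros(n_bins)
    for iv in peaks:
        h3_base[iv.start // TRACK_BIN : iv.end // TRACK_BIN] += (
            H3_SIGNAL_HEIGHT * cfg.n_cell_types
        )

    libraries, tracks = [], []
    mark_name = {"me3": "H3K27me3", "ac": "H3K27ac"}
    for s, (depth, nuclei) in enumerate(zip(cfg.depth_factors, cfg.nuclei_factors)):
        n_lambda = int(round(LAMBDA_BASE_READS * depth))
        h3_id = f"s{s}_H3"
        h3_track = SignalTrack({"chrS": h3_base * depth * nuclei}, TRACK_BIN)
        h3_lib = MarkLibrary(
            h3_id, "C14", "H3", "WT", h3_track,
            n_genome_reads=int(round(h3_base.sum() * TRACK_BIN * depth * nuclei)),
            n_lambda_reads=n_lambda,
        )
        for mark in ("me3", "ac"):
            track = SignalTrack({"chrS": base[mark] * depth * nuclei}, TRACK_BIN)
            lib = MarkLibrary(
                f"s{s}_{mark_name[mark]}", "C14", mark_name[mark], "WT", track,
                n_genome_reads=int(round(base[mark].sum() * TRACK_BIN * depth * nuclei)),
                n_lambda_reads=n_lambda,
                paired_h3_sample=h3_id,
            )
            libraries.append(lib)
            tracks.append(track)
        libraries.append(h3_lib)
    return libraries, tracks, peaks, truth


def mark_peak_sets(
    truth: SyntheticTruth, peaks: PeakSet, cell_type: str | None = None
) -> tuple[PeakSet, PeakSet]:
    """(me3, ac) peak sets for one cell type, or pooled over all types."""
    layers = sorted({ct for ct, _ in truth.mark_of})
    use = [cell_type] if cell_type is not None else layers
    me3, ac = [], []
    for iv in peaks:
        states = {truth.mark_of.get((layer, iv.id), "none") for layer in use}
        if "me3" in states:
            me3.append(iv)
        if "ac" in states:
            ac.append(iv)
    return PeakSet(me3), PeakSet(ac)


# ---------------------------------------------------------------------------
# RNAPII-S5P tracks


S5P_BODY_MEAN = 20.0  # expected signal per bin over the gene body
S5P_PROX = 300
S5P_BODY_END = 5000


def simulate_rnapii_tracks(
    cfg: SyntheticConfig,
    genes: list[GeneRecord],
    noise: bool = True,
):
    """Strand-aware S5P tracks for wild type and knockdown.

    Per eligible gene (body >= ``S5P_BODY_END`` bp) the expected signal
    is ``S5P_BODY_MEAN`` per bin over the body window and ``ratio ×
    S5P_BODY_MEAN`` over the promoter window (TSS ± 300 bp), with the
    planted ratio ``pausing_ratio_wt`` or ``pausing_ratio_kd``.  With
    ``noise=True`` each bin is Poisson-sampled; otherwise the expected
    values are returned, for exact-oracle checks.  Genes with bodies
    shorter than the body window are skipped with a warning.

    Returns ``(s5p_wt, s5p_kd, truth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    n_bins = cfg.genome_length_bp // TRACK_BIN
    truth = SyntheticTruth()
    short = [g.gene_id for g in genes if g.length < S5P_BODY_END]
    if short:
        warnings.warn(
            f"{len(short)} genes shorter than {S5P_BODY_END} bp skipped "
            f"for S5P simulation (e.g. {short[0]})"
        )
    out = {}
    for cond, ratio in (("WT", cfg.pausing_ratio_wt), ("KD", cfg.pausing_ratio_kd)):
        mean = np.zeros(n_bins)
        for g in genes:
            if g.length < S5P_BODY_END:
                continue
            truth.pausing_param[(cond, g.gene_id)] = ratio
            if g.strand == "+":
                prom = (g.tss - S5P_PROX, g.tss + S5P_PROX)
                body = (g.tss + S5P_PROX, g.tss + S5P_BODY_END)
            else:
                prom = (g.tss - S5P_PROX, g.tss + S5P_PROX)
                body = (g.tss - S5P_BODY_END, g.tss - S5P_PROX)
            mean[prom[0] // TRACK_BIN : prom[1] // TRACK_BIN] = S5P_BODY_MEAN * ratio
            mean[body[0] // TRACK_BIN : body[1] // TRACK_BIN] = S5P_BODY_MEAN
        values = rng.poisson(mean).astype(float) if noise else mean
        out[cond] = SignalTrack({"chrS": values}, TRACK_BIN)
    return out["WT"], out["KD"], truth
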