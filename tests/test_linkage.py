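import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from zgakit.genomic import CellTable, GeneRecord, GenomicInterval, PeakSet
from zgakit.linkage import (
    assign_enhancer,
    assign_promoter,
    build_cre_map,
    compare_correlations,
    kd_logfc_correlation,
    link_peaks,
    per_cell_correlation,
    per_layer_correlation,
)
from zgakit.multiome import NormalizedMatrix, normalize_rna, tfidf


def make_norm(arr, features, cells=None):
    arr = np.asarray(arr, dtype=float)
    cells = cells or [f"c{j}" for j in range(arr.shape[1])]
    return NormalizedMatrix(features, cells, sparse.csr_matrix(arr))


def toy_linkage_setup(rng, n_cells=80, n_extra=250):
    """One gene whose expression equals one peak's accessibility, plus
    uncorrelated background peaks with matched covariates."""
    acc = rng.random(n_cells) * 2
    peaks = [GenomicInterval("c", 5000, 5400, id="linked", gc=0.45)]
    rows = [acc]
    for k in range(n_extra):
        peaks.append(
            GenomicInterval(
                "c", 40_000 + 500 * k, 40_400 + 500 * k, id=f"bg{k}",
                gc=float(rng.uniform(0.4, 0.5)),
            )
        )
        rows.append(rng.random(n_cells) * 2)
    atac = make_norm(np.vstack(rows), [p.id for p in peaks])
    rna = make_norm(acc[None, :], ["gene1"])
    gene = GeneRecord("gene1", "c", 4000, "+", 12_000)
    return rna, atac, [gene], PeakSet(peaks)


class TestLinkPeaks:
    def test_perfect_coupling_significant(self, rng):
        rna, atac, genes, peaks = toy_linkage_setup(rng)
        links = link_peaks(rna, atac, genes, peaks, window=20_000, n_background=100)
        row = links[links["peak"] == "linked"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["z"] > 4
        assert row["p"] < 0.05

    def test_requires_shared_cells(self, rng):
        rna, atac, genes, peaks = toy_linkage_setup(rng)
        rna_bad = make_norm(np.zeros((1, 80)), ["gene1"],
                            cells=[f"x{j}" for j in range(80)])
        with pytest.raises(ValueError, match="same cells"):
            link_peaks(rna_bad, atac, genes, peaks)

    def test_constant_expression_skipped(self, rng):
        rna, atac, genes, peaks = toy_linkage_setup(rng)
        rna_const = make_norm(np.ones((1, 80)), ["gene1"])
        links = link_peaks(rna_const, atac, genes, peaks, n_background=100)
        assert links.empty

    def test_window_limits_candidates(self, rng):
        rna, atac, genes, peaks = toy_linkage_setup(rng)
        # only the 'linked' peak is within 20 kb of the TSS at 4000
        links = link_peaks(rna, atac, genes, peaks, window=20_000, n_background=100)
        assert set(links["peak"]) == {"linked"}


class TestAssignPromoter:
    def _atac(self):
        peaks = PeakSet(
            [
                GenomicInterval("c", 900, 1100, id="pA"),
                GenomicInterval("c", 1200, 1400, id="pB"),
                GenomicInterval("c", 9000, 9100, id="far"),
            ]
        )
        atac = make_norm([[0.3] * 4, [0.8] * 4, [1.0] * 4], peaks.ids())
        return atac, peaks

    def test_single_overlap_returned(self):
        atac, peaks = self._atac()
        gene = GeneRecord("g", "c", 1000, "+", 6000)
        only = PeakSet([peaks[0], peaks[2]])
        assert assign_promoter(atac, gene, only) == "pA"

    def test_argmax_accessibility(self):
        atac, peaks = self._atac()
        gene = GeneRecord("g", "c", 1000, "+", 6000)
        # both pA and pB overlap TSS +/- 500; pB more accessible
        assert assign_promoter(atac, gene, peaks) == "pB"

    def test_tie_breaks_lexicographically(self):
        peaks = PeakSet(
            [
                GenomicInterval("c", 900, 1100, id="pB"),
                GenomicInterval("c", 1200, 1400, id="pA"),
            ]
        )
        atac = make_norm([[0.5] * 3, [0.5] * 3], ["pB", "pA"])
        gene = GeneRecord("g", "c", 1000, "+", 6000)
        assert assign_promoter(atac, gene, peaks) == "pA"

    def test_no_overlap_returns_none(self):
        atac, peaks = self._atac()
        gene = GeneRecord("g", "c", 30_000, "+", 40_000)
        assert assign_promoter(atac, gene, peaks) is None


class TestAssignEnhancer:
    def _setup(self):
        gene = GeneRecord("g", "c", 10_000, "+", 20_000)
        peaks = PeakSet(
            [
                GenomicInterval("c", 14_800, 15_200, id="e1"),
                GenomicInterval("c", 17_000, 17_400, id="e2"),
                GenomicInterval("c", 9_700, 10_100, id="prom_ov"),
                GenomicInterval("c", 60_000, 60_400, id="distal"),
            ]
        )
        return gene, peaks

    def test_single_significant_link(self):
        gene, peaks = self._setup()
        links = pd.DataFrame(
            {"gene": ["g"], "peak": ["e1"], "r": [0.6], "z": [5.0], "p": [1e-4]}
        )
        assert assign_enhancer(links, gene, peaks) == "e1"

    def test_argmax_r_wins(self):
        gene, peaks = self._setup()
        links = pd.DataFrame(
            {
                "gene": ["g", "g"],
                "peak": ["e1", "e2"],
                "r": [0.6, 0.4],
                "z": [5, 4],
                "p": [1e-4, 1e-3],
            }
        )
        assert assign_enhancer(links, gene, peaks) == "e1"

    def test_promoter_overlap_excluded(self):
        gene, peaks = self._setup()
        links = pd.DataFrame(
            {"gene": ["g"], "peak": ["prom_ov"], "r": [0.9], "z": [9], "p": [1e-9]}
        )
        assert assign_enhancer(links, gene, peaks) is None

    def test_window_and_significance_enforced(self):
        gene, peaks = self._setup()
        links = pd.DataFrame(
            {
                "gene": ["g", "g"],
                "peak": ["distal", "e1"],
                "r": [0.9, 0.5],
                "z": [9, 1],
                "p": [1e-9, 0.4],
            }
        )
        # distal is outside +/- 20 kb; e1 is not significant
        assert assign_enhancer(links, gene, peaks) is None


class TestPerCellCorrelation:
    def _setup(self, rng, coupled=True):
        n_genes, n_cells = 12, 15
        E = rng.random((n_genes, n_cells))
        A = np.exp(E) if coupled else rng.random((n_genes, n_cells))
        genes = [f"g{i}" for i in range(n_genes)]
        prom = [f"g{i}_p" for i in range(n_genes)]
        enh = [f"g{i}_e" for i in range(n_genes)]
        rna = make_norm(E, genes)
        atac = make_norm(np.vstack([A, rng.random((n_genes, n_cells))]), enh + prom)
        cre = pd.DataFrame(
            {"gene": genes, "promoter_peak": prom, "enhancer_peak": enh}
        )
        return rna, atac, cre, genes

    def test_monotone_coupling_gives_rho_one(self, rng):
        rna, atac, cre, genes = self._setup(rng, coupled=True)
        rho = per_cell_correlation(rna, atac, cre, genes, "enhancer")
        assert np.allclose(rho, 1.0)

    def test_independent_gives_rho_near_zero(self, rng):
        rna, atac, cre, genes = self._setup(rng, coupled=False)
        rho = per_cell_correlation(rna, atac, cre, genes, "enhancer")
        assert abs(np.nanmean(rho)) < 0.25

    def test_too_few_genes_rejected(self, rng):
        rna, atac, cre, genes = self._setup(rng)
        with pytest.raises(ValueError, match=">= 3"):
            per_cell_correlation(rna, atac, cre.iloc[:2], genes, "enhancer")


class TestCompareCorrelations:
    def test_identical_samples_p_near_one(self):
        x = np.linspace(-0.5, 0.5, 20)
        _, p = compare_correlations(x, x)
        assert p > 0.9

    def test_textbook_exact(self):
        u, p = compare_correlations([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_shift_alternative_tiny_p(self, rng):
        a = rng.normal(0.1, 0.05, 500)
        b = rng.normal(0.4, 0.05, 500)
        _, p = compare_correlations(a, b)
        assert p < 1e-6


class TestPerLayerCorrelation:
    def _tables(self, e_prof, a_prof):
        layers = ["ectoderm", "endoderm", "mesoderm", "yolk"]
        cells = CellTable(
            pd.DataFrame(
                {
                    "cell_id": [f"c{i}" for i in range(4)],
                    "germ_layer": layers,
                    "genotype": "WT",
                    "replicate": "r1",
                }
            )
        )
        rna = make_norm(np.asarray(e_prof)[None, :], ["g"])
        atac = make_norm(np.asarray(a_prof)[None, :], ["pk"])
        cre = pd.DataFrame(
            {"gene": ["g"], "promoter_peak": ["pk"], "enhancer_peak": ["pk"]}
        )
        return rna, atac, cells, cre

    def test_same_peak_layer_gives_one(self):
        rna, atac, cells, cre = self._tables([5, 1, 2, 3], [9, 2, 4, 6])
        rho = per_layer_correlation(rna, atac, cells, cre, ["g"])
        assert rho["g"] == pytest.approx(1.0)

    def test_anticorrelated_gives_minus_one(self):
        rna, atac, cells, cre = self._tables([1, 2, 3, 4], [8, 6, 4, 2])
        rho = per_layer_correlation(rna, atac, cells, cre, ["g"])
        assert rho["g"] == pytest.approx(-1.0)

    def test_hand_ranked_four_layers(self):
        # expression ranks (1,3,2,4); accessibility ranks (2,3,1,4)
        # spearman = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*2/60 = 0.8
        rna, atac, cells, cre = self._tables([0.1, 0.5, 0.3, 0.9], [0.4, 0.6, 0.2, 0.8])
        rho = per_layer_correlation(rna, atac, cells, cre, ["g"])
        assert rho["g"] == pytest.approx(0.8)

    def test_constant_profile_missing(self):
        rna, atac, cells, cre = self._tables([1, 1, 1, 1], [1, 2, 3, 4])
        rho = per_layer_correlation(rna, atac, cells, cre, ["g"])
        assert np.isnan(rho["g"])


class TestKdLogfcCorrelation:
    def _frames(self, fc_atac):
        gex = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "a", "b", "c"],
                "layer": ["m", "m", "m", "e", "e", "e"],
                "log2fc": [1.0, -0.5, 2.0, 0.3, -1.2, 0.8],
            }
        )
        atac = gex.copy()
        atac["log2fc"] = fc_atac
        return gex, atac

    def test_identical_fold_changes_r_one(self):
        gex, atac = self._frames([1.0, -0.5, 2.0, 0.3, -1.2, 0.8])
        r, _ = kd_logfc_correlation(gex, atac)
        assert r == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        n = 300
        gex = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(n)], "layer": "m",
             "log2fc": rng.normal(size=n)}
        )
        atac = gex.copy()
        atac["log2fc"] = rng.normal(size=n)
        r, _ = kd_logfc_correlation(gex, atac)
        assert abs(r) < 0.15

    def test_too_few_pairs_rejected(self):
        gex, atac = self._frames([1.0, -0.5, 2.0, 0.3, -1.2, 0.8])
        with pytest.raises(ValueError):
            kd_logfc_correlation(gex.iloc[:2], atac.iloc[:2])
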