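import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from zgakit.genomic import CellTable, CountMatrix
from zgakit.multiome import (
    NormalizedMatrix,
    gene_identity_score,
    normalize_rna,
    primary_germ_layers,
    qc_filter,
    select_hvgs,
    signature_score,
    tfidf,
    wilcoxon_de,
)


def make_cells(n, layers=None, genotype="WT"):
    return CellTable(
        pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "germ_layer": layers if layers is not None else ["mesoderm"] * n,
                "genotype": genotype,
                "replicate": "r1",
            }
        )
    )


def make_matrix(arr, features=None):
    arr = np.asarray(arr)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    cells = [f"c{j}" for j in range(arr.shape[1])]
    return CountMatrix(features, cells, sparse.csr_matrix(arr))


class TestQC:
    def test_count_boundary(self):
        # cell0: 299 counts -> removed; cell1: 300 -> kept
        arr = np.zeros((300, 2), dtype=int)
        arr[:299, 0] = 1
        arr[:300, 1] = 1
        cm = make_matrix(arr)
        kept, cells = qc_filter(cm, make_cells(2), set(), min_counts=300, min_genes=200)
        assert cells.cell_ids == ["c1"]

    def test_mito_boundary_inclusive(self):
        # exactly 20% mitochondrial -> kept; just above -> removed
        feats = ["mt:a"] + [f"g{i}" for i in range(249)]
        arr = np.zeros((250, 2), dtype=int)
        arr[0, 0] = 100
        arr[1:201, 0] = 2  # total 500, mito 100 -> 0.20
        arr[0, 1] = 101
        arr[1:201, 1] = 2  # total 501, mito 101 -> 0.2016
        cm = make_matrix(arr, features=feats)
        kept, cells = qc_filter(
            cm, make_cells(2), {"mt:a"}, min_counts=300, min_genes=200
        )
        assert cells.cell_ids == ["c0"]

    def test_hand_evaluated_six_cells(self):
        # 250 genes; per cell: (total, detected, mito_frac)
        feats = ["mt:a"] + [f"g{i}" for i in range(249)]
        arr = np.zeros((250, 6), dtype=int)
        arr[1:201, 0] = 2              # keep: 400 counts, 200 genes, 0 mito
        arr[1:150, 1] = 3              # drop: 149 genes
        arr[1:201, 2] = 1              # drop: 200 counts < 300
        arr[0, 3] = 200; arr[1:201, 3] = 2   # drop: mito 200/600 = 0.33
        arr[0, 4] = 100; arr[1:201, 4] = 2   # keep: mito 100/500 = 0.20
        arr[1:250, 5] = 2              # keep: 498 counts, 249 genes
        cm = make_matrix(arr, features=feats)
        _, cells = qc_filter(cm, make_cells(6), {"mt:a"})
        assert cells.cell_ids == ["c0", "c4", "c5"]

    def test_all_removed_raises(self):
        cm = make_matrix(np.ones((5, 3), dtype=int))
        with pytest.raises(ValueError, match="review"):
            qc_filter(cm, make_cells(3), set())


class TestNormalizeRNA:
    def test_closed_form(self):
        arr = np.zeros((2, 1), dtype=int)
        arr[0, 0] = 1
        arr[1, 0] = 9999
        norm = normalize_rna(make_matrix(arr))
        # count 1 in a 10000-total cell at scale 10000 -> ln(2)
        assert norm.X[0, 0] == pytest.approx(np.log(2.0))
        assert norm.X[1, 0] == pytest.approx(np.log(1 + 9999.0))

    def test_depth_invariance(self):
        arr = np.array([[2, 4], [6, 12], [1, 2]])
        norm = normalize_rna(make_matrix(arr))
        a = np.asarray(norm.X[:, 0].todense()).ravel()
        b = np.asarray(norm.X[:, 1].todense()).ravel()
        assert np.allclose(a, b)

    def test_zero_total_cell_rejected(self):
        arr = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_rna(make_matrix(arr))


class TestTFIDF:
    def test_hand_computed_3x3(self):
        arr = np.array([[2, 0, 1], [0, 3, 0], [1, 1, 1]])
        norm = tfidf(make_matrix(arr))
        colsum = arr.sum(axis=0)
        ncells_row = (arr > 0).sum(axis=1)
        for i in range(3):
            for j in range(3):
                if arr[i, j] == 0:
                    expected = 0.0
                else:
                    expected = np.log1p(arr[i, j] / colsum[j] * 3 / ncells_row[i] * 1e4)
                assert norm.X[i, j] == pytest.approx(expected, abs=1e-6)

    def test_constant_ubiquitous_peak_constant_row(self):
        arr = np.array([[2, 2, 2], [1, 1, 1]])
        norm = tfidf(make_matrix(arr))
        row = np.asarray(norm.X[0].todense()).ravel()
        assert np.allclose(row, row[0])

    def test_empty_peak_warns_and_stays_zero(self):
        arr = np.array([[0, 0], [1, 2]])
        with pytest.warns(UserWarning, match="zero cells"):
            norm = tfidf(make_matrix(arr))
        assert norm.X[0].nnz == 0


class TestHVGs:
    def test_constant_gene_never_beats_varying(self, rng):
        arr = np.vstack([np.full(50, 5), rng.integers(0, 10, 50)])
        norm = normalize_rna(make_matrix(arr + 1))  # +1 keeps cells non-zero
        assert select_hvgs(norm, n=1) == ["g1"]

    def test_full_selection_is_identity_set(self, small_multiome):
        rna, *_ = small_multiome
        norm = normalize_rna(rna)
        assert set(select_hvgs(norm, n=len(norm.features))) == set(norm.features)

    def test_planted_variable_genes_recovered(self, rng):
        n_cells = 200
        flat = rng.poisson(2.0, size=(30, n_cells))
        bimodal = rng.poisson(12.0, size=(5, n_cells)) * rng.integers(0, 2, (5, n_cells))
        arr = np.vstack([flat, bimodal]) + 1
        feats = [f"flat{i}" for i in range(30)] + [f"hv{i}" for i in range(5)]
        norm = normalize_rna(make_matrix(arr, features=feats))
        top = select_hvgs(norm, n=5)
        assert set(top) == {f"hv{i}" for i in range(5)}


class TestSignatureScore:
    def test_random_set_scores_near_zero(self, small_multiome):
        rna, *_ = small_multiome
        norm = normalize_rna(rna)
        rng = np.random.default_rng(5)
        genes = list(rng.choice(norm.features, size=6, replace=False))
        sc = signature_score(norm, genes, seed=1)
        assert abs(sc.mean()) < 0.15

    def test_markers_score_higher_in_own_layer(self, small_multiome):
        rna, _, cells, genes, _, truth = small_multiome
        norm = normalize_rna(rna)
        for layer, markers in truth.marker_genes.items():
            sc = signature_score(norm, sorted(markers), seed=1)
            own = sc[cells.germ_layer == layer].mean()
            other = sc[cells.germ_layer != layer].mean()
            assert own > other

    def test_deterministic_given_seed(self, small_multiome):
        rna, *_ = small_multiome
        norm = normalize_rna(rna)
        genes = norm.features[:5]
        assert np.array_equal(
            signature_score(norm, genes, seed=7), signature_score(norm, genes, seed=7)
        )

    def test_absent_genes_listed_in_error(self, small_multiome):
        rna, *_ = small_multiome
        norm = normalize_rna(rna)
        with pytest.raises(ValueError, match="nope"):
            signature_score(norm, ["nope"], seed=0)


class TestWilcoxonDE:
    def test_null_permutation_calibrated(self, rng):
        n_genes, n_cells = 150, 120
        arr = rng.poisson(3.0, size=(n_genes, n_cells)) + 1
        norm = normalize_rna(make_matrix(arr))
        cells = make_cells(n_cells)
        labels = rng.permutation(np.arange(n_cells) % 2)
        df = wilcoxon_de(norm, cells, labels == 0, labels == 1)
        frac_sig = (df["p"] < 0.05).mean()
        assert 0.005 <= frac_sig <= 0.12
        assert np.all(df["q"] >= df["p"] - 1e-12)

    def test_low_expression_gene_excluded(self):
        arr = np.ones((3, 200), dtype=int)
        arr[0] = 0
        arr[0, 0] = 5  # g0 detected in 0.5% of group A cells only
        norm = normalize_rna(make_matrix(arr + np.array([[0]] * 3)))
        cells = make_cells(200)
        groups = np.arange(200) < 100
        df = wilcoxon_de(norm, cells, groups, ~groups)
        assert "g0" not in set(df["gene"])

    def test_shifted_gene_detected(self, rng):
        arr = rng.poisson(2.0, size=(40, 300)) + 1
        arr[0, :150] += 8
        norm = normalize_rna(make_matrix(arr))
        cells = make_cells(300)
        groups = np.arange(300) < 150
        df = wilcoxon_de(norm, cells, groups, ~groups).set_index("gene")
        assert df.loc["g0", "q"] < 1e-6
        assert df.loc["g0", "log2fc"] > 0

    def test_small_group_rejected(self):
        arr = np.ones((5, 10), dtype=int)
        norm = normalize_rna(make_matrix(arr))
        with pytest.raises(ValueError, match="3 cells"):
            wilcoxon_de(norm, make_cells(10), np.arange(10) < 2, np.arange(10) >= 2)


class TestGeneIdentity:
    def _norm(self, arr, layers):
        arr = np.asarray(arr, dtype=float)
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(arr.shape[0])],
            [f"c{j}" for j in range(arr.shape[1])],
            sparse.csr_matrix(np.asarray(arr, dtype=float)),
        )
        return norm, make_cells(arr.shape[1], layers=layers)

    def test_exclusive_gene_scores_one(self):
        layers = ["mesoderm"] * 3 + ["ectoderm"] * 3
        norm, cells = self._norm([[1, 1, 1, 0, 0, 0]], layers)
        primary = primary_germ_layers(norm, cells, ["g0"])
        assert primary == {"g0": "mesoderm"}
        df = gene_identity_score(norm, cells, ["g0"], primary)
        assert df.loc[0, "score"] == 1.0

    def test_uniform_gene_scores_quarter(self):
        layers = sum([[l] * 3 for l in ["mesoderm", "ectoderm", "endoderm", "yolk"]], [])
        arr = np.ones((1, 12))
        arr[0, 0] = 2.0  # break the argmax tie toward mesoderm
        norm, cells = self._norm(arr, layers)
        primary = primary_germ_layers(norm, cells, ["g0"])
        df = gene_identity_score(norm, cells, ["g0"], primary)
        assert df.loc[0, "score"] == pytest.approx(0.25)

    def test_hand_counted_twelve_cells(self):
        layers = ["mesoderm"] * 4 + ["ectoderm"] * 4 + ["endoderm"] * 4
        # g0: expressed in 3 meso + 1 ecto -> primary mesoderm, score 3/4
        arr = np.zeros((1, 12))
        arr[0, [0, 1, 2, 4]] = [5, 1, 2, 1]
        norm, cells = self._norm(arr, layers)
        primary = primary_germ_layers(norm, cells, ["g0"])
        df = gene_identity_score(norm, cells, ["g0"], primary)
        assert df.loc[0, "primary_layer"] == "mesoderm"
        assert df.loc[0, "score"] == pytest.approx(0.75)
        assert df.loc[0, "n_expressing"] == 4

    def test_invariance_to_order_and_scale(self, rng):
        layers = ["mesoderm"] * 5 + ["ectoderm"] * 5
        arr = rng.random((3, 10))
        norm, cells = self._norm(arr, layers)
        primary = primary_germ_layers(norm, cells, ["g0", "g1", "g2"])
        base = gene_identity_score(norm, cells, ["g0", "g1", "g2"], primary)
        norm2, _ = self._norm(arr * 7.5, layers)
        scaled = gene_identity_score(norm2, cells, ["g0", "g1", "g2"], primary)
        assert np.allclose(base["score"], scaled["score"])
        perm = rng.permutation(10)
        norm3 = NormalizedMatrix(norm.features, [norm.cells[i] for i in perm],
                                 norm.X[:, perm])
        cells3 = make_cells(10, layers=[layers[i] for i in perm])
        permuted = gene_identity_score(norm3, cells3, ["g0", "g1", "g2"], primary)
        assert np.allclose(base["score"], permuted["score"])

    def test_unexpressed_gene_reported_missing(self):
        layers = ["mesoderm"] * 2 + ["ectoderm"] * 2
        norm, cells = self._norm(np.zeros((1, 4)), layers)
        df = gene_identity_score(norm, cells, ["g0"], {"g0": "mesoderm"})
        assert np.isnan(df.loc[0, "score"])
        assert df.loc[0, "n_expressing"] == 0
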