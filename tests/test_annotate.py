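import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurotrace import annotate as ann
from neurotrace.annotate import ReferenceAtlas

from conftest import make_normalized


def toy_atlas(centroids: dict, gene_ids=None):
    n = len(next(iter(centroids.values())))
    gene_ids = gene_ids or [f"mm:g{i:03d}" for i in range(n)]
    return ReferenceAtlas(
        centroids=pd.DataFrame(centroids, index=pd.Index(gene_ids, name="gene_id"))
    )


class TestHVGs:
    def test_tie_break_is_lexicographic(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        values = np.tile(base, (6, 1))  # 6 genes x 8 cells, all rows identical
        nm = make_normalized(values, gene_ids=[f"g{i}" for i in range(6)])
        assert ann.find_hvgs(nm, 3) == ["g0", "g1", "g2"]

    def test_high_variance_gene_ranked_first(self):
        rng = np.random.default_rng(1)
        values = rng.normal(5, 0.1, size=(20, 50))
        noisy = rng.normal(0, 1.0, size=50)
        values[7] = 5 + noisy - noisy.mean()  # 10x the spread at equal mean
        nm = make_normalized(values)
        assert ann.find_hvgs(nm, 1)[0] == "mm:g007"

    def test_n_equals_total(self):
        nm = make_normalized(np.random.default_rng(0).normal(size=(5, 4)))
        assert sorted(ann.find_hvgs(nm, 5)) == sorted(nm.gene_ids)

    def test_n_too_large_errors(self):
        nm = make_normalized(np.ones((3, 4)))
        with pytest.raises(ValueError):
            ann.find_hvgs(nm, 10)


class TestLabelTransfer:
    def test_hand_computed_three_gene_toy(self):
        nm = make_normalized(np.array([[1.0], [2.0], [3.0]]), gene_ids=["a", "b", "c"])
        atlas = toy_atlas({"A": [1, 2, 3], "B": [3, 2, 1]}, gene_ids=["a", "b", "c"])
        res = ann.label_transfer(nm, atlas, ["a", "b", "c"]).table.iloc[0]
        assert res.best_type == "A"
        assert res.best_corr == pytest.approx(1.0)
        assert res.runner_up == "B"
        assert res.margin == pytest.approx(2.0)

    def test_query_equal_to_centroid(self, neuron_normalized, reference_atlas, neuron_hvgs):
        genes = sorted(
            set(neuron_hvgs) & set(reference_atlas.centroids.index)
        )
        profile = reference_atlas.centroids.loc[genes, "PEP"].to_numpy()[:, None]
        nm = make_normalized(profile, gene_ids=genes)
        res = ann.label_transfer(nm, reference_atlas, genes).table.iloc[0]
        assert res.best_type == "PEP" and res.best_corr == pytest.approx(1.0)
        assert res.margin > 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(10)]
        q = rng.normal(size=(10, 3))
        cents = {"A": rng.normal(size=10), "B": rng.normal(size=10)}
        a1 = ann.label_transfer(
            make_normalized(q, gene_ids=genes), toy_atlas(cents, genes), genes
        )
        perm = rng.permutation(10)
        a2 = ann.label_transfer(
            make_normalized(q[perm], gene_ids=[genes[i] for i in perm]),
            toy_atlas({k: v[perm] for k, v in cents.items()}, [genes[i] for i in perm]),
            genes,
        )
        pd.testing.assert_frame_equal(a1.table, a2.table)

    def test_constant_profile_unassignable(self):
        nm = make_normalized(np.ones((5, 1)))
        atlas = toy_atlas({"A": np.arange(5.0), "B": np.arange(5.0)[::-1]})
        res = ann.label_transfer(nm, atlas, list(nm.gene_ids))
        assert res.labels.iloc[0] == ann.UNASSIGNABLE

    def test_too_small_intersection_errors(self):
        nm = make_normalized(np.ones((2, 1)), gene_ids=["a", "b"])
        atlas = toy_atlas({"A": [1.0, 2.0]}, gene_ids=["a", "b"])
        with pytest.raises(ValueError, match="shared"):
            ann.label_transfer(nm, atlas, ["a", "b"])

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        q = rng.normal(size=(30, 5))
        cents = {"A": rng.normal(size=30), "B": rng.normal(size=30)}
        res = ann.label_transfer(
            make_normalized(q, gene_ids=genes), toy_atlas(cents, genes), genes
        )
        for ci in range(5):
            expected = max(
                ("A", stats.pearsonr(q[:, ci], cents["A"]).statistic),
                ("B", stats.pearsonr(q[:, ci], cents["B"]).statistic),
                key=lambda t: t[1],
            )
            assert res.table.best_type.iloc[ci] == expected[0]
            assert res.table.best_corr.iloc[ci] == pytest.approx(expected[1])


class TestSecondAnnotator:
    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        cent = rng.normal(size=20)
        atlas = toy_atlas({"A": cent, "B": rng.normal(size=20)}, genes)
        q = np.exp(cent)[:, None]  # monotone transform of centroid A
        res = ann.second_annotator(make_normalized(q, gene_ids=genes), atlas, genes)
        assert res.table.best_type.iloc[0] == "A"
        assert res.table.best_corr.iloc[0] == pytest.approx(1.0)

    def test_same_toy_as_pearson(self):
        nm = make_normalized(np.array([[1.0], [2.0], [3.0]]), gene_ids=["a", "b", "c"])
        atlas = toy_atlas({"A": [1, 2, 3], "B": [3, 2, 1]}, gene_ids=["a", "b", "c"])
        assert ann.second_annotator(nm, atlas, ["a", "b", "c"]).labels.iloc[0] == "A"

    def test_constant_profile_unassignable(self):
        nm = make_normalized(np.full((5, 1), 2.0))
        atlas = toy_atlas({"A": np.arange(5.0), "B": np.arange(5.0)[::-1]})
        res = ann.second_annotator(nm, atlas, list(nm.gene_ids))
        assert res.labels.iloc[0] == ann.UNASSIGNABLE


class TestConcordance:
    def _assign(self, labels):
        return ann.Assignment(
            table=pd.DataFrame(
                {"best_type": labels, "best_corr": 1.0, "runner_up": "",
                 "margin": 0.1, "tied": False},
                index=pd.Index([f"c{i}" for i in range(len(labels))], name="cell_id"),
            )
        )

    def test_identical_assignments(self):
        a = self._assign(["A", "B", "A"])
        rate, _ = ann.concordance(a, a)
        assert rate == 1.0

    def test_complete_disagreement(self):
        rate, _ = ann.concordance(
            self._assign(["A"] * 4), self._assign(["B"] * 4)
        )
        assert rate == 0.0

    def test_unassignable_excluded(self):
        rate, _ = ann.concordance(
            self._assign(["A", ann.UNASSIGNABLE]), self._assign(["A", "B"])
        )
        assert rate == 1.0

    def test_disjoint_cells_error(self):
        a = self._assign(["A"])
        b = ann.Assignment(table=a.table.rename(index={"c0": "x0"}))
        with pytest.raises(ValueError):
            ann.concordance(a, b)

    def test_synthetic_recovery(self, neuron_experiment, neuron_normalized,
                                reference_atlas, neuron_hvgs):
        """Both annotators recover planted subpopulations, and agree."""
        _, _, truth = neuron_experiment
        a = ann.label_transfer(neuron_normalized, reference_atlas, neuron_hvgs)
        b = ann.second_annotator(neuron_normalized, reference_atlas, neuron_hvgs)
        accuracy = (a.labels == truth.cells.subpopulation).mean()
        rate, _ = ann.concordance(a, b)
        assert accuracy >= 0.95
        assert rate >= 0.95


class TestClustering:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        X = np.hstack(
            [rng.normal(0, 0.1, (20, 25)), rng.normal(5, 0.1, (20, 25))]
        )
        labels = ann.snn_louvain(make_normalized(X), n_pcs=10, k=5, seed=0)
        assert labels.max() + 1 == 2
        assert len(set(labels[:25])) == 1 and len(set(labels[25:])) == 1

    def test_duplication_preserves_co_membership(self):
        rng = np.random.default_rng(1)
        X = np.hstack(
            [rng.normal(0, 0.1, (10, 15)), rng.normal(4, 0.1, (10, 15))]
        )
        Xd = np.hstack([X, X])
        ids = [f"c{i}" for i in range(60)]
        labels = ann.snn_louvain(
            make_normalized(Xd, cell_ids=ids), n_pcs=5, k=5, seed=0
        )
        # each cell and its duplicate land in the same cluster
        assert (labels[:30] == labels[30:]).all()

    def test_seeded_determinism(self, neuron_normalized, neuron_hvgs):
        l1 = ann.snn_louvain(neuron_normalized, n_pcs=20, k=10, seed=3, hvgs=neuron_hvgs)
        l2 = ann.snn_louvain(neuron_normalized, n_pcs=20, k=10, seed=3, hvgs=neuron_hvgs)
        assert (l1 == l2).all()

    def test_modularity_beats_trivial_partition(self, neuron_normalized, neuron_hvgs):
        # any returned partition must improve on the single-cluster partition,
        # whose modularity is 0
        import igraph

        labels = ann.snn_louvain(neuron_normalized, n_pcs=20, k=10, seed=3,
                                 hvgs=neuron_hvgs)
        assert labels.max() + 1 >= 2

    def test_k_too_large_errors(self):
        nm = make_normalized(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError, match="k="):
            ann.snn_louvain(nm, n_pcs=2, k=4, seed=0)


class TestComposition:
    def _assignment(self, labels, ids):
        return ann.Assignment(
            table=pd.DataFrame(
                {"best_type": labels, "best_corr": 1.0, "runner_up": "",
                 "margin": 0.1, "tied": False},
                index=pd.Index(ids, name="cell_id"),
            )
        )

    def test_single_type(self):
        a = self._assignment(["A", "A"], ["c0", "c1"])
        cells = pd.DataFrame({"condition": ["healthy", "healthy"]},
                             index=pd.Index(["c0", "c1"], name="cell_id"))
        table = ann.composition_table(a, cells)
        assert table[("proportion", "A")].iloc[0] == 1.0

    def test_151_cell_split(self):
        labels = ["A"] * 100 + ["B"] * 51
        ids = [f"c{i}" for i in range(151)]
        a = self._assignment(labels, ids)
        cells = pd.DataFrame({"condition": ["tumour"] * 151},
                             index=pd.Index(ids, name="cell_id"))
        table = ann.composition_table(a, cells)
        assert table[("proportion", "A")].iloc[0] == pytest.approx(0.6623, abs=1e-4)
        assert table[("proportion", "B")].iloc[0] == pytest.approx(0.3377, abs=1e-4)

    def test_rows_sum_to_one(self, neuron_experiment, neuron_normalized,
                             reference_atlas, neuron_hvgs):
        _, cm, _ = neuron_experiment
        a = ann.label_transfer(neuron_normalized, reference_atlas, neuron_hvgs)
        table = ann.composition_table(a, cm.cells)
        assert np.allclose(table["proportion"].sum(axis=1), 1.0)
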