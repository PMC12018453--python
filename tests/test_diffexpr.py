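import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurotrace import diffexpr as de
from neurotrace import synthetic_data as syn

from conftest import make_count_matrix, make_normalized


class TestPseudobulk:
    def test_single_cell_groups_equal_cells(self):
        cm = make_count_matrix(
            [[1, 3], [2, 4]],
            cells={"replicate": ["H1", "T1"], "condition": ["healthy", "tumour"]},
        )
        pb = de.make_pseudobulk(cm)
        assert pb.counts.to_numpy().tolist() == [[1, 3], [2, 4]]

    def test_summation(self):
        cm = make_count_matrix(
            [[1, 3], [2, 4]],
            cells={"replicate": ["H1", "H1"], "condition": ["healthy", "healthy"]},
        )
        pb = de.make_pseudobulk(cm)
        assert pb.counts.iloc[:, 0].tolist() == [4, 6]
        assert pb.meta.n_cells.iloc[0] == 2

    def test_split_and_merge_conserves_totals(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(30, 12))
        reps = ["H1"] * 6 + ["H2"] * 6
        subpop = (["a", "b"] * 6)[:12]
        cm = make_count_matrix(
            counts,
            cells={"replicate": reps, "condition": ["healthy"] * 12,
                   "subpopulation": subpop},
        )
        coarse = de.make_pseudobulk(cm, ("replicate", "condition"))
        fine = de.make_pseudobulk(cm, ("replicate", "condition", "subpopulation"))
        assert np.array_equal(
            coarse.counts.sum(axis=1).to_numpy(), fine.counts.sum(axis=1).to_numpy()
        )

    def test_missing_column_errors(self):
        cm = make_count_matrix([[1]])
        with pytest.raises(ValueError, match="replicate"):
            de.make_pseudobulk(cm)


@pytest.fixture(scope="module")
def null_pseudobulk():
    cfg = syn.SimConfig(seed=11, n_genes=2000, fraction_low_quality_cells=0.0)
    cm, _ = syn.generate_neuron_experiment(cfg)
    return de.make_pseudobulk(cm)


class TestNBWald:
    def test_identical_libraries_are_null(self):
        counts = pd.DataFrame(
            {f"L{i}": [10, 50, 200] for i in range(5)},
            index=["g1", "g2", "g3"],
        )
        meta = pd.DataFrame(
            {"condition": ["healthy", "healthy", "tumour", "tumour", "tumour"],
             "replicate": list("abcde"), "n_cells": 1},
            index=counts.columns,
        )
        res = de.nb_wald_test(de.PseudobulkTable(counts=counts, meta=meta))
        assert np.allclose(res.table.log2FC, 0.0, atol=1e-8)
        assert (res.table.pvalue > 0.99).all()

    def test_condition_swap_negates_lfc(self, null_pseudobulk):
        a = de.nb_wald_test(null_pseudobulk, ("tumour", "healthy"))
        b = de.nb_wald_test(null_pseudobulk, ("healthy", "tumour"))
        assert np.allclose(a.table.log2FC, -b.table.log2FC, atol=1e-6)
        assert np.allclose(a.table.pvalue, b.table.pvalue, atol=1e-9)

    def test_null_type_one_error_calibrated(self, null_pseudobulk):
        res = de.nb_wald_test(null_pseudobulk)
        frac = (res.table.pvalue < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_poisson_limit(self):
        """At dispersion -> 0 the Wald z agrees with a Poisson GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(40.0, size=(50, 5)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"L{i}" for i in range(5)],
        )
        meta = pd.DataFrame(
            {"condition": ["healthy"] * 2 + ["tumour"] * 3,
             "replicate": list("abcde"), "n_cells": 1},
            index=counts.columns,
        )
        pb = de.PseudobulkTable(counts=counts, meta=meta)
        sf = de.pseudobulk_size_factors(counts)
        alpha = np.full(50, 1e-8)
        beta, se = de._nb_irls(counts.to_numpy(float), np.array([0, 0, 1, 1, 1], bool),
                               np.log(sf), alpha)
        x = sm.add_constant(np.array([0, 0, 1, 1, 1.0]))
        for g in range(0, 50, 10):
            fit = sm.GLM(counts.iloc[g].to_numpy(), x, family=sm.families.Poisson(),
                         offset=np.log(sf)).fit()
            assert beta[g, 1] / se[g] == pytest.approx(
                fit.params[1] / fit.bse[1], abs=1e-3
            )

    def test_power_on_planted_genes(self):
        idx_up = tuple(range(400, 450))
        idx_dn = tuple(range(450, 500))
        allp = ("CG1", "CG2", "NEFM", "PEP", "NPEP")
        cfg = syn.SimConfig(
            seed=21, n_genes=2000, fraction_low_quality_cells=0.0,
            de_base_mean_range=(50.0, 2000.0),
            de_gene_sets=(syn.DEGeneSet(idx_up, allp, 2.0),
                          syn.DEGeneSet(idx_dn, allp, -2.0)),
        )
        cm, truth = syn.generate_neuron_experiment(cfg)
        res = de.nb_wald_test(de.make_pseudobulk(cm))
        tab = res.table.set_index("gene")
        planted = truth.genes.index[list(idx_up + idx_dn)]
        eligible = [g for g in planted if truth.genes.base_mean[g] >= 50]
        sensitivity = (tab.loc[eligible, "padj"] < 0.1).mean()
        assert sensitivity >= 0.9
        assert (tab.loc[truth.genes.index[list(idx_up)], "log2FC"] > 0).all()

    def test_agrees_with_pydeseq2_on_fold_changes(self):
        """Independent cross-check: log2FC tracks a reference NB pipeline."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = syn.SimConfig(
            seed=33, n_genes=300, marker_genes_per_subpop=10,
            fraction_low_quality_cells=0.0,
            de_gene_sets=(syn.DEGeneSet(tuple(range(100, 120)),
                                        ("CG1", "CG2", "NEFM", "PEP", "NPEP"), 2.0),),
        )
        cm, _ = syn.generate_neuron_experiment(cfg)
        pb = de.make_pseudobulk(cm)
        mine = de.nb_wald_test(pb).table.set_index("gene")

        counts = pb.counts.T
        clinical = pd.DataFrame({"condition": pb.meta.condition.to_numpy()},
                                index=counts.index)
        dds = DeseqDataSet(counts=counts, metadata=clinical,
                           design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "tumour", "healthy"],
                           quiet=True)
        stats.summary()
        ref = stats.results_df["log2FoldChange"].reindex(mine.index)
        ok = ref.notna() & (mine.baseMean > 5)
        r = np.corrcoef(mine.loc[ok, "log2FC"], ref[ok])[0, 1]
        assert r > 0.95

    def test_too_few_libraries_names_fallback(self):
        counts = pd.DataFrame({"L0": [1], "L1": [2], "L2": [3]}, index=["g"])
        meta = pd.DataFrame(
            {"condition": ["healthy", "tumour", "tumour"],
             "replicate": list("abc"), "n_cells": 1},
            index=counts.columns,
        )
        with pytest.raises(ValueError, match="[Ww]ilcoxon"):
            de.nb_wald_test(de.PseudobulkTable(counts=counts, meta=meta))


class TestWilcoxon:
    def _nm(self, values, groups):
        nm = make_normalized(values)
        return nm, pd.Series(groups, index=nm.cell_ids)

    def test_exact_enumeration_example(self):
        nm, groups = self._nm(
            [[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]],
            ["tumour"] * 3 + ["healthy"] * 3,
        )
        res = de.wilcoxon_de(nm, groups)
        assert res.table.pvalue.iloc[0] == pytest.approx(0.1)

    def test_enumeration_oracle(self):
        """Exact p equals brute-force enumeration over all C(6,3) splits."""
        x = np.array([1.2, 3.4, 0.5, 7.7, 5.1, 2.2])
        obs_u = sum(
            1 for a in x[:3] for b in x[3:] if a > b
        )
        null = []
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            u = sum(1 for i in comb for j in rest if x[i] > x[j])
            null.append(u)
        mean_u = 4.5
        p_expected = np.mean(
            [abs(u - mean_u) >= abs(obs_u - mean_u) for u in null]
        )
        nm, groups = self._nm([x], ["tumour"] * 3 + ["healthy"] * 3)
        assert de.wilcoxon_de(nm, groups).table.pvalue.iloc[0] == pytest.approx(
            p_expected
        )

    def test_identical_groups_p_one(self):
        nm, groups = self._nm(
            [[2.0, 2.0, 2.0, 2.0]], ["tumour"] * 2 + ["healthy"] * 2
        )
        assert de.wilcoxon_de(nm, groups).table.pvalue.iloc[0] == 1.0

    def test_rank_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=24)
        nm1, groups = self._nm([x], ["tumour"] * 12 + ["healthy"] * 12)
        nm2, _ = self._nm([np.exp(x)], ["tumour"] * 12 + ["healthy"] * 12)
        assert de.wilcoxon_de(nm1, groups).table.pvalue.iloc[0] == pytest.approx(
            de.wilcoxon_de(nm2, groups).table.pvalue.iloc[0]
        )

    def test_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        from scipy import stats

        p_exact = stats.mannwhitneyu(x[:10], x[10:], alternative="two-sided",
                                     method="exact").pvalue
        p_asym = stats.mannwhitneyu(x[:10], x[10:], alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.02

    def test_small_group_errors(self):
        nm, groups = self._nm([[1.0, 2.0, 3.0]], ["tumour", "healthy", "healthy"])
        with pytest.raises(ValueError, match="at least 2"):
            de.wilcoxon_de(nm, groups)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_applied_step_up(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        assert np.allclose(
            de.bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_capped_and_order_preserving(self, pvals):
        adj = de.bh_adjust(pvals)
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()
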