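import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

import drgcomm as dc
from drgcomm.de import _wilcoxon_columns, bh_adjust, p_adjust, wilcoxon_rank_sum

from helpers import exact_wilcoxon_p, toy_adata


class TestWilcoxon:
    def test_worked_examples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)
        _, p = wilcoxon_rank_sum([1, 2], [3, 4, 5])
        assert p == pytest.approx(0.2, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 4), min_size=1, max_size=6),
        st.lists(st.integers(0, 4), min_size=1, max_size=6),
    )
    def test_matches_enumeration_oracle_small(self, x, y):
        """Exact path agrees with an independent full enumeration, ties included."""
        if len(x) + len(y) > 10:
            x = x[:5]
            y = y[:5]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.integers(0, 6, size=rng.integers(8, 40)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(8, 40)).astype(float)
            _, p = wilcoxon_rank_sum(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert p == pytest.approx(min(1.0, ref), rel=1e-9)

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(1)
        X1 = rng.integers(0, 4, size=(15, 30)).astype(float)
        X2 = rng.integers(0, 4, size=(12, 30)).astype(float)
        p_vec = _wilcoxon_columns(X1, X2)
        p_ref = [wilcoxon_rank_sum(X1[:, j], X2[:, j])[1] for j in range(30)]
        np.testing.assert_allclose(p_vec, p_ref, atol=1e-12)


class TestBH:
    def test_worked_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.05, 0.05]), [0.05, 0.05])

    def test_permutation_equivariant_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1.0, 40)
        perm = rng.permutation(40)
        adj = bh_adjust(p)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-15)
        assert (adj <= 1).all() and (adj >= p).all()

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 50))
            ref = statsmodels.multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    def test_bonferroni_option(self):
        np.testing.assert_allclose(p_adjust([0.01, 0.4], "bonferroni"), [0.02, 0.8])


class TestDeTable:
    @staticmethod
    def _two_group_adata(counts0, counts1):
        counts = np.vstack([counts0, counts1])
        n0, n1 = len(counts0), len(counts1)
        return toy_adata(counts, timepoints=[0.0] * n0 + [0.5] * n1)

    def test_null_gene_fold_near_one(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, size=(40, 20))
        adata = self._two_group_adata(counts[:20], counts[20:])
        tab = dc.de_table(adata, "TypeA", 0.5)
        assert len(tab) == 20
        assert np.median(tab.fold_change) == pytest.approx(1.0, abs=0.35)
        assert (tab.p_value > 0.01).mean() > 0.8

    def test_absent_gene_excluded(self):
        counts = np.ones((10, 3), dtype=int)
        counts[:, 2] = 0
        adata = self._two_group_adata(counts[:5], counts[5:])
        tab = dc.de_table(adata, "TypeA", 0.5)
        assert set(tab.gene) == {"g0", "g1"}

    def test_insufficient_cells_skips_with_warning(self, caplog):
        counts = np.ones((4, 3), dtype=int)
        adata = self._two_group_adata(counts[:2], counts[2:])
        with caplog.at_level(logging.WARNING):
            tab = dc.de_table(adata, "TypeA", 0.5)
        assert len(tab) == 0
        assert "skipping DE" in caplog.text

    def test_planted_fold_recovered(self, planted_small):
        """A ligand planted at fold 5 with 100 cells/group is estimated
        within the expected window and clearly significant."""
        adata, truth = planted_small
        pi = truth.planted_interactions[0]
        tab = dc.de_table(adata, pi.sender, 0.5)
        row = tab[tab.gene == pi.ligand].iloc[0]
        assert 3.5 <= row.fold_change <= 6.5
        assert row.p_value < 0.05
        assert pi.ligand in dc.select_lr_candidates(tab)


class TestSelection:
    @staticmethod
    def _records(**overrides):
        base = dict(gene=["g"], cell_type=["T"], timepoint=[0.5], fold_change=[4.0],
                    log2_fc=[2.0], pct_expr_group=[0.5], pct_expr_ref=[0.1],
                    p_value=[0.01], adj_p=[0.02])
        base.update({k: [v] for k, v in overrides.items()})
        return pd.DataFrame(base)

    def test_lr_candidate_boundaries_strict(self):
        assert dc.select_lr_candidates(self._records()) == {"g"}
        assert dc.select_lr_candidates(self._records(fold_change=3.0)) == set()
        assert dc.select_lr_candidates(self._records(pct_expr_group=0.09)) == set()
        assert dc.select_lr_candidates(self._records(p_value=0.05)) == set()

    def test_pseudobulk_boundary_strict(self):
        assert dc.select_pseudobulk_de(self._records(adj_p=1e-21)) == {"g"}
        assert dc.select_pseudobulk_de(self._records(adj_p=1e-20)) == set()
        assert dc.select_pseudobulk_de(pd.DataFrame()) == set()
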