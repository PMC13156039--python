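import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import drgcomm as dc
from drgcomm.interactome import (
    InteractionActivity,
    build_candidate_pairs,
    enrichment_score,
    interactome_table,
    sankey_export,
    score_interaction,
    stratified_background,
    validate_lr_reference,
)
from drgcomm.io import LOGNORM_LAYER

from helpers import toy_adata


class TestReference:
    def test_parse_and_validate(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("ligand\treceptor\ttargets\nIl6\tIl6ra\ta;b;c\n")
        ref = dc.read_lr_reference(path)
        assert ref.targets[0] == ("a", "b", "c")

    def test_duplicate_pair_rejected(self):
        ref = pd.DataFrame({"ligand": ["L", "L"], "receptor": ["R", "R"],
                            "targets": ["a", "b"]})
        with pytest.raises(ValueError, match="duplicate"):
            validate_lr_reference(ref)

    def test_empty_targets_rejected(self):
        ref = pd.DataFrame({"ligand": ["L"], "receptor": ["R"], "targets": [""]})
        with pytest.raises(ValueError, match="empty target"):
            validate_lr_reference(ref)


class TestCandidatePairs:
    @staticmethod
    def _adata():
        # 10 cells of A, 10 of B; receptor g1 detected in 50% of B,
        # receptor g2 in 10% of B (not > 10%: excluded)
        counts = np.zeros((20, 4), dtype=int)
        counts[:, 0] = 1  # ligand expressed everywhere
        counts[10:15, 1] = 2
        counts[10, 2] = 2
        counts[:, 3] = 1
        return toy_adata(counts, cell_types=["A"] * 10 + ["B"] * 10)

    def _ref(self):
        return validate_lr_reference(pd.DataFrame({
            "ligand": ["g0", "g0", "absent"],
            "receptor": ["g1", "g2", "g3"],
            "targets": ["g3", "g3", "g3"],
        }))

    def test_pair_emitted_when_receptor_detected(self):
        pairs = build_candidate_pairs({"A": {"g0"}}, self._adata(), self._ref())
        assert [tuple(r) for r in pairs.itertuples(index=False)] == [("A", "B", "g0", "g1")]

    def test_no_pair_below_detection_threshold(self):
        pairs = build_candidate_pairs({"A": {"g0"}}, self._adata(), self._ref())
        assert "g2" not in set(pairs.receptor)

    def test_empty_up_sets(self):
        pairs = build_candidate_pairs({}, self._adata(), self._ref())
        assert len(pairs) == 0

    def test_absent_reference_genes_skipped(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="drgcomm.interactome"):
            build_candidate_pairs({"A": {"absent"}}, self._adata(), self._ref())
        assert "skipped 1" in caplog.text


class TestStratifiedBackground:
    @staticmethod
    def _adata(n_genes=2040, n_cells=30):
        rng = np.random.default_rng(0)
        return toy_adata(rng.poisson(2, size=(n_cells, n_genes)))

    def test_partition_property(self):
        adata = self._adata()
        pool = {f"g{j}" for j in range(40)}
        params = dc.PipelineParams(n_background_intervals=20, genes_per_interval=100)
        bg = stratified_background(pool, adata, None, np.random.default_rng(1), params)
        assert bg.shape == (20, 100)
        flat = bg.ravel()
        assert len(set(flat)) == 2000
        assert not pool & set(flat)

    def test_deterministic_given_rng(self):
        adata = self._adata()
        bg1 = stratified_background(set(), adata, None, np.random.default_rng(5))
        bg2 = stratified_background(set(), adata, None, np.random.default_rng(5))
        np.testing.assert_array_equal(bg1, bg2)

    def test_clamping_with_warning(self):
        adata = self._adata()
        pool = {f"g{j}" for j in range(2000)}  # leaves 40 background genes
        with pytest.warns(UserWarning, match="drawing 2 per interval"):
            bg = stratified_background(pool, adata, None, np.random.default_rng(2))
        assert bg.shape == (20, 2)

    def test_too_few_background_genes(self):
        adata = self._adata(n_genes=30)
        pool = {f"g{j}" for j in range(25)}
        with pytest.raises(ValueError, match="background genes"):
            stratified_background(pool, adata, None, np.random.default_rng(0))


class TestEnrichmentScore:
    @staticmethod
    def _constructed(delta=0.5):
        """Associated genes exceed every background gene by delta in every cell."""
        n_cells, n_genes = 8, 60
        adata = toy_adata(np.ones((n_cells, n_genes), dtype=int))
        layer = np.full((n_cells, n_genes), 0.2)
        layer[:, :5] = 0.2 + delta  # associated genes
        adata.layers[LOGNORM_LAYER] = sp.csr_matrix(layer)
        return adata

    def test_constant_offset_recovered_exactly(self):
        adata = self._constructed(delta=0.5)
        bg = np.array([[f"g{j}" for j in range(5, 25)]] * 2)
        s = enrichment_score(adata, None, None, [f"g{j}" for j in range(5)], bg)
        assert s == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_scores_zero(self):
        adata = toy_adata(np.ones((4, 20), dtype=int))
        adata.layers[LOGNORM_LAYER] = sp.csr_matrix(np.zeros((4, 20)))
        s = enrichment_score(adata, None, None, ["g0"], np.array([["g1", "g2"]]))
        assert s == 0.0

    def test_zero_associated_positive_background_negative(self):
        adata = self._constructed()
        layer = np.asarray(adata.layers[LOGNORM_LAYER].todense())
        layer[:, :5] = 0.0
        adata.layers[LOGNORM_LAYER] = sp.csr_matrix(layer)
        s = enrichment_score(adata, None, None, [f"g{j}" for j in range(5)],
                             np.array([["g10", "g11"]]))
        assert s < 0

    def test_no_receiver_cells_errors(self):
        adata = self._constructed()
        with pytest.raises(ValueError, match="no receiver cells"):
            enrichment_score(adata, "Missing", None, ["g0"], np.array([["g1"]]))

    def test_empty_associated_errors(self):
        adata = self._constructed()
        with pytest.raises(ValueError, match="associated"):
            enrichment_score(adata, None, None, ["nope"], np.array([["g1"]]))


class TestScoreInteraction:
    def test_negative_replicates_clip_to_zero(self):
        """All-zero associated genes against positive background: every
        replicate is negative, activity is exactly 0."""
        rng = np.random.default_rng(0)
        n_cells, n_genes = 10, 600
        counts = rng.poisson(3, size=(n_cells, n_genes))
        counts[:, 0] = 0  # associated gene silent
        adata = toy_adata(counts)
        params = dc.PipelineParams(n_background_intervals=5, genes_per_interval=20)
        act = score_interaction(
            adata,
            {"sender": "TypeA", "receiver": "TypeA", "ligand": "gL", "receptor": "gR"},
            0.0, ["g0"], set(), params, np.random.default_rng(1),
        )
        assert all(r < 0 for r in act.replicate_scores)
        assert act.activity_score == 0.0

    def test_positive_replicates_average(self):
        adata = toy_adata(np.ones((6, 200), dtype=int))
        layer = np.full((6, 200), 0.1)
        layer[:, 0] = 0.6
        adata.layers[LOGNORM_LAYER] = sp.csr_matrix(layer)
        params = dc.PipelineParams(n_background_intervals=5, genes_per_interval=20)
        act = score_interaction(
            adata,
            {"sender": "TypeA", "receiver": "TypeA", "ligand": "gL", "receptor": "gR"},
            0.0, ["g0"], {"g0"}, params, np.random.default_rng(1),
        )
        assert act.activity_score == pytest.approx(0.5, abs=1e-9)
        assert act.activity_score == pytest.approx(np.mean(np.maximum(act.replicate_scores, 0)))
        assert len(act.replicate_scores) == params.n_score_replicates


def _activity(sender, receiver, ligand, receptor, score):
    return InteractionActivity(sender, receiver, 0.5, ligand, receptor,
                               score, (score,) * 5, 100)


class TestOutputs:
    def test_table_sorted_with_lexicographic_ties(self):
        acts = [
            _activity("B", "A", "l1", "r1", 0.5),
            _activity("A", "B", "l2", "r2", 0.5),
            _activity("A", "A", "l3", "r3", 0.9),
        ]
        table = interactome_table(acts)
        assert list(table.sender_type) == ["A", "A", "B"]
        assert table.activity_score.iloc[0] == 0.9

    def test_sankey_all_zero_no_links(self):
        assert sankey_export([_activity("A", "B", "l", "r", 0.0)])["links"] == []

    def test_sankey_single_positive(self):
        out = sankey_export([_activity("A", "B", "l", "r", 0.25)])
        assert out["links"] == [
            {"source": "A", "target": "B", "ligand": "l", "receptor": "r", "value": 0.25}
        ]
        assert [n["name"] for n in out["nodes"]] == ["A", "B"]
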