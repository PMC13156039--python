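import numpy as np
import pytest

import drgcomm as dc
from drgcomm.io import read_dataset
from drgcomm.simulate import read_truth


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = dc.default_config(seed=3, n_cell_types=5, cells_per_type_per_timepoint=20,
                                timepoints=(0.0, 0.5), n_genes=400)
        a1, t1 = dc.simulate_dataset(cfg)
        a2, t2 = dc.simulate_dataset(cfg)
        np.testing.assert_array_equal(
            np.asarray(a1.X.todense()), np.asarray(a2.X.todense())
        )
        assert list(a1.obs_names) == list(a2.obs_names)
        assert (a1.obs == a2.obs).all().all()
        assert t1.module_cell_ids == t2.module_cell_ids

    def test_different_seed_differs(self):
        cfg = dc.null_config(n_cell_types=3, cells_per_type_per_timepoint=10,
                             timepoints=(0.0, 0.5), n_genes=200)
        a1, _ = dc.simulate_dataset(dc.null_config(seed=1, n_cell_types=3,
                                                   cells_per_type_per_timepoint=10,
                                                   timepoints=(0.0, 0.5), n_genes=200))
        a2, _ = dc.simulate_dataset(dc.null_config(seed=2, n_cell_types=3,
                                                   cells_per_type_per_timepoint=10,
                                                   timepoints=(0.0, 0.5), n_genes=200))
        assert (np.asarray(a1.X.todense()) != np.asarray(a2.X.todense())).any()


class TestNullStructure:
    def test_mean_expression_timepoint_independent(self, null_desk):
        """Without planted effects the expected per-type expression profile
        does not change over time (within sampling error)."""
        from drgcomm.io import get_lognorm

        adata, _ = null_desk
        L = get_lognorm(adata)
        tps = adata.obs["timepoint"].astype(float).to_numpy()
        for ct in ("Fibroblast", "PEP1"):
            mask = (adata.obs["cell_type"] == ct).to_numpy()
            m0 = np.asarray(L[mask & (tps == 0.0)].mean(axis=0)).ravel()
            m1 = np.asarray(L[mask & (tps == 12.0)].mean(axis=0)).ravel()
            # library-normalized profiles are stable over time
            assert abs(np.log(m1.sum() / m0.sum())) < 0.1
            hi = m0 > 0.2
            assert np.corrcoef(m0[hi], m1[hi])[0, 1] > 0.95


class TestPlantedStructure:
    def test_truth_composition_matches_paper_fold(self, desk_sim):
        """Planted monocyte fractions 3.5% -> 65% give the ~18.6-fold influx."""
        _, truth = desk_sim
        tab = truth.composition_table
        mono = tab[tab.cell_type == "Monocyte"].set_index("timepoint")["fraction"]
        assert mono[0.0] == pytest.approx(0.035)
        assert mono[0.5] == pytest.approx(0.65)
        assert mono[0.5] / mono[0.0] == pytest.approx(18.571, abs=0.01)

    def test_truth_fractions_sum_to_one(self, desk_sim):
        _, truth = desk_sim
        sums = truth.composition_table.groupby(["timepoint", "compartment"])["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_realized_monocyte_peak(self, desk_sim):
        adata, _ = desk_sim
        obs = adata.obs
        imm = obs[obs.compartment == "immune"]
        at_peak = imm[imm.timepoint.astype(float) == 0.5]
        frac = (at_peak.cell_type == "Monocyte").mean()
        assert 0.55 < frac < 0.75

    def test_planted_genes_in_universe(self, desk_sim):
        adata, truth = desk_sim
        for pi in truth.planted_interactions:
            for g in (pi.ligand, pi.receptor, *pi.targets):
                assert g in adata.var_names

    def test_high_mito_cells_flaggable(self, desk_sim):
        adata, _ = desk_sim
        qc = dc.compute_qc(adata)
        frac_high = (qc.mito_fraction > 0.2).mean()
        assert 0.02 < frac_high < 0.09  # ~5% damaged cells planted


class TestConfigValidation:
    def test_role_collision_rejected(self):
        pi = dc.PlantedInteraction("Fibroblast", "Macrophage", "Il6", "Il6ra",
                                   ("Il6",), 5.0, (0.5,))
        with pytest.raises(ValueError, match="Il6"):
            dc.SimulationConfig(planted_interactions=(pi,))

    def test_timepoints_must_contain_zero(self):
        with pytest.raises(ValueError, match="timepoint 0"):
            dc.SimulationConfig(timepoints=(0.5, 1.0))

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError, match="monocyte_fraction_peak"):
            dc.SimulationConfig(monocyte_fraction_peak=1.5)

    def test_nonpositive_fold_rejected(self):
        pi = dc.PlantedInteraction("Fibroblast", "Macrophage", "Il6", "Il6ra",
                                   ("T1",), -1.0, (0.5,))
        with pytest.raises(ValueError, match="fold"):
            dc.SimulationConfig(planted_interactions=(pi,))


class TestFixtureIO:
    def test_write_fixture_roundtrip(self, tmp_path):
        cfg = dc.default_config(seed=4, n_cell_types=5, cells_per_type_per_timepoint=10,
                                timepoints=(0.0, 0.5), n_genes=300)
        adata, truth = dc.simulate_dataset(cfg)
        paths = dc.write_fixture(adata, truth, tmp_path)
        assert sorted(p.name for p in paths) == [
            "cells.tsv", "genes.tsv", "matrix.mtx", "truth.json",
        ]
        back = read_dataset(tmp_path)
        np.testing.assert_array_equal(
            np.asarray(adata.X.todense()), np.asarray(back.X.todense())
        )
        t2 = read_truth(tmp_path)
        assert t2.planted_interactions == truth.planted_interactions
        assert t2.module_genes == truth.module_genes
        assert t2.module_cell_ids == truth.module_cell_ids

    def test_write_fixture_refuses_overwrite(self, tmp_path):
        cfg = dc.null_config(seed=4, n_cell_types=2, cells_per_type_per_timepoint=5,
                             timepoints=(0.0,), n_genes=100, markers_per_type=2)
        adata, truth = dc.simulate_dataset(cfg)
        dc.write_fixture(adata, truth, tmp_path)
        with pytest.raises(FileExistsError):
            dc.write_fixture(adata, truth, tmp_path)
        dc.write_fixture(adata, truth, tmp_path, force=True)
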