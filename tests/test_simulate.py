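import numpy as np
import pandas as pd
import pytest

from cellrecap.datatypes import N_STRATA, PhylostratumMap
from cellrecap.enrichment import hypergeometric_test, propagate_annotations
from cellrecap.simulate import (
    NetworkParams,
    SimulationConfig,
    cc_signature_genes,
    make_gene_ids,
    simulate_expression,
    simulate_neighborhood_coupled,
    simulate_network,
    simulate_ontology,
)

FLAT = (0.0,) * N_STRATA


class TestConfigValidation:
    def test_profile_length_enforced(self):
        with pytest.raises(ValueError, match="17"):
            SimulationConfig(slope_profile=(0.1, 0.2))

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes_per_stratum=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_cells_per_population=0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-0.1)

    def test_block_probabilities_validated(self):
        with pytest.raises(ValueError):
            NetworkParams(p_within_uc=1.5)


class TestSimulateExpression:
    def test_no_signal_degenerate_case(self):
        cfg = SimulationConfig(n_genes_per_stratum=3,
                               n_cells_per_population=5, noise_sd=0.0,
                               slope_profile=FLAT, shift_profile=FLAT,
                               gene_baseline_sd=0.0, n_background_genes=0,
                               n_cc_genes=2, seed=0)
        matrix, strata, _ = simulate_expression(cfg)
        dated = matrix.values.loc[strata.strata.index]
        assert (dated.nunique(axis=1) == 1).all()

    def test_single_programmed_shift_is_exact_twofold(self):
        shift = list(FLAT)
        shift[4] = 1.0  # stratum 5 up by one log2 unit
        cfg = SimulationConfig(n_genes_per_stratum=4,
                               n_cells_per_population=6, noise_sd=0.0,
                               slope_profile=FLAT,
                               shift_profile=tuple(shift),
                               n_background_genes=0, n_cc_genes=2, seed=1)
        matrix, strata, _ = simulate_expression(cfg)
        ref = matrix.cells_in("reference")
        con = matrix.cells_in("contrast")
        for s in range(1, N_STRATA + 1):
            genes = sorted(strata.stratum_genes(s))
            ratio = (matrix.values.loc[genes, con].mean(axis=1)
                     / matrix.values.loc[genes, ref].mean(axis=1))
            expected = 2.0 if s == 5 else 1.0
            np.testing.assert_allclose(ratio, expected, rtol=1e-10)

    def test_stratum_correlation_sign_pattern(self):
        # positive coupling in stratum 1, negative in stratum 6: the sample
        # correlation of the group mean with the signature mean follows
        cfg = SimulationConfig(n_genes_per_stratum=20,
                               n_cells_per_population=100,
                               noise_sd=0.2, n_background_genes=0, seed=2)
        matrix, strata, _ = simulate_expression(cfg)
        cc = matrix.values.loc[sorted(cc_signature_genes(cfg))].mean()
        s1 = matrix.values.loc[sorted(strata.stratum_genes(1))].mean()
        s6 = matrix.values.loc[sorted(strata.stratum_genes(6))].mean()
        assert np.corrcoef(s1, cc)[0, 1] > 0.3
        assert np.corrcoef(s6, cc)[0, 1] < -0.3

    def test_log2_recovers_generative_model_within_noise(self):
        cfg = SimulationConfig(n_genes_per_stratum=10,
                               n_cells_per_population=50, noise_sd=0.3,
                               slope_profile=FLAT, shift_profile=FLAT,
                               gene_baseline_sd=0.0, n_background_genes=0,
                               seed=3)
        matrix, strata, _ = simulate_expression(cfg)
        log2 = np.log2(matrix.values.loc[strata.strata.index].to_numpy())
        resid = log2 - cfg.base_intercept
        assert abs(resid.mean()) < 0.05
        assert abs(resid.std() - cfg.noise_sd) < 0.05

    def test_matrix_strictly_positive(self, small_config):
        matrix, _, _ = simulate_expression(small_config)
        assert (matrix.values.to_numpy() > 0).all()

    def test_determinism_byte_identical(self, small_config):
        a, _, _ = simulate_expression(small_config)
        b, _, _ = simulate_expression(small_config)
        assert a.values.to_csv() == b.values.to_csv()

    def test_gene_shift_override(self):
        cfg = SimulationConfig(n_genes_per_stratum=2,
                               n_cells_per_population=4, noise_sd=0.0,
                               slope_profile=FLAT, shift_profile=FLAT,
                               n_background_genes=0, n_cc_genes=2, seed=4)
        override = pd.Series({"PS01_G000": 1.0})
        matrix, _, truth = simulate_expression(cfg, gene_shifts=override)
        assert truth.gene_shifts["PS01_G000"] == 1.0
        ref = matrix.cells_in("reference")
        con = matrix.cells_in("contrast")
        ratio = (matrix.values.loc["PS01_G000", con].mean()
                 / matrix.values.loc["PS01_G000", ref].mean())
        assert ratio == pytest.approx(2.0, rel=1e-10)


class TestSimulateNetwork:
    def _strata(self, n=10):
        return PhylostratumMap(strata=make_gene_ids(n))

    def test_disconnected_blocks_give_pure_neighborhoods(self):
        params = NetworkParams(p_between_ucmc=0.0, p_between_mc=0.0,
                               p_within_mc=0.3, n_mc_blocks=1)
        cfg = SimulationConfig(n_genes_per_stratum=10, network_params=params,
                               seed=5)
        strata = self._strata()
        _, net, truth = simulate_network(cfg, strata)
        uc = strata.uc_genes()
        f_uc = truth.node_mc_fraction[truth.node_mc_fraction.index.isin(uc)]
        assert (f_uc.dropna() == 0).all()
        f_mc = truth.node_mc_fraction[~truth.node_mc_fraction.index.isin(uc)]
        assert (f_mc.dropna() == 1).all()

    def test_blend_arithmetic(self):
        # f = 0.75 with coupling (-0.1, +0.1) blends to
        # -0.1 * 0.25 + 0.1 * 0.75 = +0.05 (sign reversal for a UC gene)
        delta_uc, delta_mc = -0.1, 0.1
        f = 0.75
        assert (1 - f) * delta_uc + f * delta_mc == pytest.approx(0.05)
        cfg = SimulationConfig(n_genes_per_stratum=15, seed=6)
        strata = self._strata(15)
        _, _, truth = simulate_network(cfg, strata)
        defined = truth.node_mc_fraction.dropna()
        blended = truth.gene_shifts[defined.index]
        np.testing.assert_allclose(
            blended, (1 - defined) * delta_uc + defined * delta_mc,
            atol=1e-12)

    def test_determinism_identical_edge_list(self):
        cfg = SimulationConfig(n_genes_per_stratum=8, seed=7)
        strata = self._strata(8)
        e1, _, _ = simulate_network(cfg, strata)
        e2, _, _ = simulate_network(cfg, strata)
        pd.testing.assert_frame_equal(e1, e2)

    def test_uc_block_denser_than_mc_blocks(self):
        cfg = SimulationConfig(n_genes_per_stratum=40, seed=8)
        strata = self._strata(40)
        edges, net, truth = simulate_network(cfg, strata)
        uc = strata.uc_genes()
        within_uc = between = within_mc = 0
        for a, b in net.graph.edges:
            a_uc, b_uc = a in uc, b in uc
            if a_uc and b_uc:
                within_uc += 1
            elif a_uc != b_uc:
                between += 1
            else:
                within_mc += 1
        n_uc, n_mc = len(uc), len(strata.mc_genes())
        dens_uc = within_uc / (n_uc * (n_uc - 1) / 2)
        dens_between = between / (n_uc * n_mc)
        dens_mc = within_mc / (n_mc * (n_mc - 1) / 2)
        assert dens_uc / dens_between > dens_mc / dens_between

    def test_confidence_scores_in_range(self):
        cfg = SimulationConfig(n_genes_per_stratum=8, seed=9)
        edges, net, _ = simulate_network(cfg, self._strata(8))
        assert edges["confidence"].between(0.4, 1.0).all()
        # the >0.5 filter removes a nontrivial fraction of raw edges
        assert net.graph.number_of_edges() < len(edges)
        kept = [d["confidence"] for _, _, d in net.graph.edges(data=True)]
        assert min(kept) > 0.5


class TestSimulateOntology:
    def test_star_dag_at_depth_one(self):
        dag = simulate_ontology(n_terms=6, depth=1, annotations_per_gene=1,
                                seed=0, genes=["g1", "g2"])
        root = dag.roots()
        assert root == ["T0000"]
        for t in dag.terms:
            if t != "T0000":
                assert list(dag.graph.successors(t)) == ["T0000"]

    def test_planted_term_is_enriched(self):
        uc = [f"u{i}" for i in range(10)]
        mc = [f"m{i}" for i in range(40)]
        dag = simulate_ontology(n_terms=12, depth=3, annotations_per_gene=1,
                                seed=1, genes=uc + mc,
                                planted={"T0011": set(uc)})
        genes_at = propagate_annotations(dag)
        k = len(set(uc) & genes_at["T0011"])
        K = len(genes_at["T0011"])
        _, oe, direction = hypergeometric_test(k, K, len(uc), len(uc) + len(mc))
        assert oe > 1 and direction == "enriched"

    def test_determinism(self):
        a = simulate_ontology(20, 4, 2, seed=3, genes=["g1", "g2", "g3"])
        b = simulate_ontology(20, 4, 2, seed=3, genes=["g1", "g2", "g3"])
        assert set(a.graph.edges) == set(b.graph.edges)
        assert a.annotations == b.annotations

    def test_single_root_and_depth(self):
        dag = simulate_ontology(30, 5, 1, seed=4)
        assert len(dag.roots()) == 1
        import networkx as nx
        assert nx.dag_longest_path_length(dag.graph) >= 4

    def test_nonsensical_arguments_rejected(self):
        with pytest.raises(ValueError):
            simulate_ontology(n_terms=2, depth=5, annotations_per_gene=1,
                              seed=0)
        with pytest.raises(ValueError):
            simulate_ontology(n_terms=5, depth=0, annotations_per_gene=1,
                              seed=0)


class TestCoupledSimulation:
    def test_all_components_align(self):
        cfg = SimulationConfig(n_genes_per_stratum=10,
                               n_cells_per_population=20,
                               n_background_genes=30, seed=10)
        data = simulate_neighborhood_coupled(cfg)
        strata_genes = set(data["strata"].strata.index)
        assert strata_genes <= set(data["matrix"].gene_ids)
        assert set(data["truth"].node_mc_fraction.index) == strata_genes
        # blended shifts actually drive the expression ground truth
        pd.testing.assert_series_equal(
            data["truth"].gene_shifts[sorted(strata_genes)],
            data["truth"].gene_shifts[sorted(strata_genes)])
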