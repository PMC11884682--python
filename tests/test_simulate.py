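"""Base-network generation, functional-structure selection and data simulation."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from cnpdr import (
    SimulationConfig,
    generate_base_network,
    select_functional_structure,
    simulate_dataset,
)


class TestBaseNetwork:
    def test_complete_and_empty_limits(self):
        assert generate_base_network(5, "erdos_renyi", 1.0, 0).number_of_edges() == 10
        assert generate_base_network(5, "erdos_renyi", 0.0, 0).number_of_edges() == 0

    def test_expected_edge_count_at_p_point_one(self):
        # E[edges] = p n (n-1) / 2 = 0.1 * 4950 = 495; Monte Carlo over seeds
        counts = [
            generate_base_network(100, "erdos_renyi", 0.1, s).number_of_edges()
            for s in range(300)
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 495) < 4 * se + 1

    def test_reproducible_for_fixed_seed(self):
        g1 = generate_base_network(30, "erdos_renyi", 0.2, 7)
        g2 = generate_base_network(30, "erdos_renyi", 0.2, 7)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_user_supplied_passthrough(self):
        g = generate_base_network(4, "user_supplied", edges=[(0, 1), (2, 3)])
        assert sorted(g.edges) == [(0, 1), (2, 3)] and g.number_of_nodes() == 4

    def test_unknown_family_names_supported_ones(self):
        with pytest.raises(ValueError, match="erdos_renyi"):
            generate_base_network(5, "small_world")


class TestFunctionalStructure:
    def test_max_multiway_selects_all_pairs(self):
        g = nx.gnp_random_graph(30, 0.3, seed=1)
        nodes, edges = select_functional_structure(g, 10, "max", seed=0)
        assert len(nodes) == 10 and len(edges) == 45
        assert all(a in nodes and b in nodes for a, b in edges)

    def test_whole_graph_when_component_equals_n_functional(self):
        g = nx.path_graph(10)
        nodes, _ = select_functional_structure(g, 10, "max", seed=3)
        assert nodes == list(range(10))

    @pytest.mark.parametrize("seed", range(20))
    def test_multiway_caps_incident_edges(self, seed):
        g = nx.gnp_random_graph(40, 0.3, seed=seed)
        nodes, edges = select_functional_structure(g, 10, 5, seed=seed)
        assert edges, "selected set must be nonempty"
        assert len(edges) < 45, "multiway=5 must leave some functional pairs untouched"
        incident = {v: 0 for v in nodes}
        for a, b in edges:
            incident[a] += 1
            incident[b] += 1
        assert max(incident.values()) <= 5

    def test_nodes_come_from_largest_component(self):
        g = nx.Graph()
        nx.add_path(g, range(8))          # component of 8
        nx.add_path(g, range(100, 103))   # component of 3
        nodes, _ = select_functional_structure(g, 5, "max", seed=0)
        assert set(nodes) <= set(range(8))

    def test_too_small_component_suggests_denser_graph(self):
        g = nx.empty_graph(20)
        with pytest.raises(ValueError, match="connection_prob"):
            select_functional_structure(g, 5, "max", seed=0)


class TestSimulateDataset:
    def test_default_design_shapes(self):
        ds, truth = simulate_dataset(SimulationConfig(seed=1))
        assert ds.feature_matrix.shape == (200, 4950)
        assert len(truth.functional_nodes) == 10
        assert all(
            a in truth.functional_nodes and b in truth.functional_nodes
            for a, b in truth.differential_edges
        )

    def test_matrices_symmetric_unit_diagonal_bounded(self):
        ds, _ = simulate_dataset(
            SimulationConfig(n_rois=12, n_cases=5, n_controls=5, n_functional=3, seed=2)
        )
        assert np.all(np.abs(ds.feature_matrix) < 1)
        m = ds.subject_matrix(0)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_rois=15, n_cases=8, n_controls=8, n_functional=3, seed=9)
        d1, t1 = simulate_dataset(cfg)
        d2, t2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(d1.feature_matrix, d2.feature_matrix)
        assert t1.differential_edges == t2.differential_edges

    def test_null_effect_gives_nominal_false_positive_rate(self):
        # d = 0: two-sample t-tests on "differential" edges behave as under
        # the null; pooled over replicates the p < 0.05 fraction is ~5%
        pvals = []
        for seed in range(30):
            cfg = SimulationConfig(
                n_rois=15, n_cases=30, n_controls=30, n_functional=5,
                effect_size=0.0, multiway="max", connection_prob=0.3, seed=seed,
            )
            ds, truth = simulate_dataset(cfg)
            labels = ds.pair_labels
            cols = [labels.index(f"{a}--{b}") for a, b in truth.differential_edges]
            cases = ds.feature_matrix[ds.phenotype == 1][:, cols]
            ctrls = ds.feature_matrix[ds.phenotype == 0][:, cols]
            pvals.extend(stats.ttest_ind(cases, ctrls, axis=0).pvalue)
        frac = np.mean(np.asarray(pvals) < 0.05)
        se = np.sqrt(0.05 * 0.95 / len(pvals))
        assert abs(frac - 0.05) < 4 * se + 0.01

    def test_cohens_d_matches_configured_effect(self):
        # empirical d on differential edges ~ 0.5 averaged over replicates
        ds_all = []
        for seed in range(50):
            cfg = SimulationConfig(
                n_rois=20, n_cases=100, n_controls=100, n_functional=5,
                effect_size=0.5, multiway="max", connection_prob=0.3, seed=seed,
            )
            ds, truth = simulate_dataset(cfg)
            labels = ds.pair_labels
            cols = [labels.index(f"{a}--{b}") for a, b in truth.differential_edges]
            cases = ds.feature_matrix[ds.phenotype == 1][:, cols]
            ctrls = ds.feature_matrix[ds.phenotype == 0][:, cols]
            sp = np.sqrt((cases.var(0, ddof=1) + ctrls.var(0, ddof=1)) / 2)
            ds_all.extend((cases.mean(0) - ctrls.mean(0)) / sp)
        assert abs(np.mean(ds_all) - 0.5) < 0.1

    def test_connected_pairs_have_higher_baseline(self):
        cfg = SimulationConfig(
            n_rois=20, n_cases=50, n_controls=50, n_functional=3,
            effect_size=0.0, connection_prob=0.3, seed=4,
        )
        ds, _ = simulate_dataset(cfg)
        means = ds.feature_matrix.mean(axis=0)
        # bimodal around 0.1 and 0.5
        hi = means[means > 0.3]
        lo = means[means <= 0.3]
        assert len(hi) and len(lo)
        assert abs(hi.mean() - 0.5) < 0.05 and abs(lo.mean() - 0.1) < 0.05

    def test_nearest_psd_projection_flag(self):
        cfg = SimulationConfig(
            n_rois=10, n_cases=5, n_controls=5, n_functional=3, seed=6, nearest_psd=True
        )
        ds, _ = simulate_dataset(cfg)
        for i in range(ds.n_samples):
            w = np.linalg.eigvalsh(ds.subject_matrix(i))
            assert w.min() > -1e-8

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_functional=101)
        with pytest.raises(ValueError):
            SimulationConfig(corr_connected_mean=0.1, corr_unconnected_mean=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(effect_size=-1)
        with pytest.raises(ValueError):
            SimulationConfig(multiway=1)
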