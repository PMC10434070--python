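"""Network construction, topology panel, null ensembles, stability, roles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lakeco import network as nw
from lakeco.io import AbundanceTable


def _table(counts):
    counts = np.asarray(counts)
    return AbundanceTable(
        tuple(f"t{i}" for i in range(counts.shape[0])),
        tuple(f"s{j}" for j in range(counts.shape[1])),
        counts,
    )


def _block_correlation(rng, block=30, within=(0.5, 0.95), between=0.1, noise=0.03):
    """Two-block correlation matrix: strong heterogeneous within-block
    correlations, weak noisy between-block ones."""
    n = 2 * block
    r = rng.normal(between, noise, size=(n, n))
    for lo in (0, block):
        w = rng.uniform(*within, size=(block, block))
        r[lo : lo + block, lo : lo + block] = w
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    ids = [f"t{i}" for i in range(n)]
    return pd.DataFrame(r, index=ids, columns=ids)


class TestPrevalenceFilter:
    @pytest.mark.parametrize("occupied,kept", [(4, True), (3, False)])
    def test_forty_percent_cutoff(self, occupied, kept):
        counts = np.zeros((2, 10), int)
        counts[0, :occupied] = 5
        counts[1, :] = 1  # keeps the table non-degenerate
        out = nw.filter_prevalence(_table(counts), 0.4)
        assert ("t0" in out.taxon_ids) == kept

    def test_zero_fraction_is_identity(self):
        table = _table([[1, 0], [0, 2]])
        out = nw.filter_prevalence(table, 0.0)
        assert out.taxon_ids == table.taxon_ids

    def test_nothing_survives_reports_counts(self):
        counts = np.zeros((2, 10), int)
        counts[:, 0] = 1
        with pytest.raises(ValueError, match="max occupancy 1"):
            nw.filter_prevalence(_table(counts), 0.4)


class TestCorrelation:
    def test_textbook_pearson_on_log_counts(self):
        counts = np.array(
            [[1, 7, 19, 4], [2, 10, 40, 3], [50, 3, 1, 8], [5, 5, 5, 5]]
        )
        corr = nw.correlation_matrix(_table(counts))
        assert "t3" not in corr.index  # zero variance after log transform
        logs = np.log1p(counts[:3].astype(float))
        expected = np.corrcoef(logs)
        np.testing.assert_allclose(corr.to_numpy(), expected, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_affine_related_transformed_vectors(self):
        # exp(x)-1 style counts whose log1p vectors are affine → r = 1
        x = np.array([0.0, 1.0, 2.0, 3.0])
        counts = np.column_stack(
            [np.expm1(x), np.expm1(2 * x + 1)]
        ).T.round().astype(int)
        corr = nw.correlation_matrix(_table(counts))
        assert corr.iloc[0, 1] == pytest.approx(1.0, abs=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nw.correlation_matrix(_table([[1, 2, 3], [3, 2, 1]]))


class TestRmtThreshold:
    def test_identity_matrix_falls_back(self):
        ids = [f"t{i}" for i in range(30)]
        corr = pd.DataFrame(np.eye(30), index=ids, columns=ids)
        with pytest.warns(UserWarning, match="fallback"):
            t = nw.rmt_threshold(corr)
        assert t == 0.8

    def test_planted_two_block(self, rng):
        corr = _block_correlation(rng)
        t = nw.rmt_threshold(corr)
        assert 0.1 < t <= 0.9
        net = nw.build_network(corr, t)
        assert nx.number_connected_components(net) == 2

    def test_goe_spectrum_rejected_as_poisson(self, rng):
        # dense random symmetric matrix: NNSD is Wigner, not Poisson
        m = rng.normal(size=(500, 500))
        fit = nw._nnsd_chi2(np.linalg.eigvalsh((m + m.T) / np.sqrt(2)))
        chi2_poisson, chi2_goe = fit
        assert chi2_goe < chi2_poisson


class TestBuildNetwork:
    def test_direct_thresholding_and_signs(self):
        ids = list("abc")
        r = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, -0.95], [0.2, -0.95, 1.0]])
        corr = pd.DataFrame(r, index=ids, columns=ids)
        net = nw.build_network(corr, 0.8)
        assert net.number_of_edges() == 2
        assert net["a"]["b"]["sign"] == 1
        assert net["b"]["c"]["sign"] == -1
        panel = nw.topology_panel(net)
        assert panel.positive_edge_fraction == pytest.approx(0.5)

    def test_monotone_in_threshold(self, rng):
        corr = _block_correlation(rng, block=10, noise=0.1)
        edge_counts = []
        for t in (0.9, 0.6, 0.3):
            try:
                edge_counts.append(nw.build_network(corr, t).number_of_edges())
            except ValueError:
                edge_counts.append(0)
        assert edge_counts == sorted(edge_counts)

    def test_empty_graph_rejected(self):
        ids = list("ab")
        corr = pd.DataFrame(np.eye(2), index=ids, columns=ids)
        with pytest.raises(ValueError):
            nw.build_network(corr, 0.5)


class TestModulesAndPanel:
    def test_two_disjoint_cliques_modularity_half(self):
        net = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        modules, q = nw.detect_modules(net, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(modules.values())) == 2

    def test_complete_graph_single_module(self):
        _, q = nw.detect_modules(nx.complete_graph(6), seed=0)
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_triangle_panel(self):
        panel = nw.topology_panel(nx.complete_graph(3))
        assert panel.average_clustering_coefficient == pytest.approx(1.0)
        assert panel.average_path_distance == pytest.approx(1.0)
        assert panel.transitivity == pytest.approx(1.0)
        assert panel.connectedness == pytest.approx(1.0)
        assert panel.average_degree == pytest.approx(2.0)

    def test_path_graph_hand_enumeration(self):
        panel = nw.topology_panel(nx.path_graph(3))
        assert panel.average_path_distance == pytest.approx(4 / 3)
        assert panel.geodesic_efficiency == pytest.approx(5 / 6)
        assert panel.harmonic_geodesic_distance == pytest.approx(3 / 2.5)

    def test_disconnected_pair_counting(self):
        net = nx.Graph([("a", "b"), ("c", "d")])
        panel = nw.topology_panel(net)
        assert panel.connectedness == pytest.approx(2 / 6)
        assert panel.geodesic_efficiency == pytest.approx(2 / 6)


class TestMaslovSneppen:
    def test_degree_multiset_preserved(self, rng):
        net = nx.gnm_random_graph(30, 90, seed=4)
        rewired = nw.maslov_sneppen(net, n_swaps_per_edge=100, seed=0)
        assert sorted(d for _, d in net.degree()) == sorted(
            d for _, d in rewired.degree()
        )
        assert not nx.utils.graphs_equal(net, rewired)

    def test_star_has_no_valid_swap(self):
        star = nx.star_graph(5)
        # exhaustive check: every candidate swap collides with the hub
        for (a, b), (c, d) in itertools.combinations(star.edges, 2):
            assert len({a, b, c, d}) < 4 or star.has_edge(a, d) or star.has_edge(c, b)
        with pytest.warns(UserWarning, match="unchanged"):
            rewired = nw.maslov_sneppen(star, seed=0)
        assert nx.utils.graphs_equal(star, rewired)

    def test_modular_graph_exceeds_ensemble(self):
        # empirical modularity > random mean + 2 sd for a clearly modular graph
        net = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        net.add_edge(0, 8)
        _, q = nw.detect_modules(net, seed=0)
        ensemble = nw.random_ensemble_panel(net, n_random=30, seed=1)
        assert q > ensemble.loc["modularity", "mean"] + 2 * ensemble.loc["modularity", "sd"]


class TestNaturalConnectivity:
    def test_isolated_nodes_zero(self):
        net = nx.empty_graph(7)
        assert nw.natural_connectivity(net) == pytest.approx(0.0)

    def test_triangle_eigen_oracle(self):
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert nw.natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize("n", range(4, 11))
    def test_complete_graph_closed_form(self, n):
        expected = np.log((np.exp(n - 1) + (n - 1) * np.exp(-1)) / n)
        assert nw.natural_connectivity(nx.complete_graph(n)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_strictly_increasing_in_n(self):
        values = [nw.natural_connectivity(nx.complete_graph(n)) for n in range(3, 11)]
        assert (np.diff(values) > 0).all()


class TestRobustness:
    def test_zero_removal_matches_intact(self):
        net = nx.gnm_random_graph(20, 40, seed=1)
        rc = nw.robustness_curve(net, fractions=[0.0, 0.2], n_reps=10, seed=0)
        first = rc.curve.iloc[0]
        biggest = max(nx.connected_components(net), key=len)
        assert first["lcc_mean"] == pytest.approx(len(biggest) / 20)
        assert first["lcc_sd"] == 0.0
        assert first["nat_conn_mean"] == pytest.approx(nw.natural_connectivity(net))

    def test_complete_graph_never_fragments(self):
        rc = nw.robustness_curve(
            nx.complete_graph(12), fractions=np.arange(0, 0.8, 0.1), n_reps=20, seed=0
        )
        np.testing.assert_allclose(rc.curve["lcc_mean"], 1.0)
        assert rc.auc == pytest.approx(1.0)

    def test_star_fragmentation_matches_expectation(self):
        # remove 1 of N nodes: hub removed w.p. 1/N → LCC fraction collapses
        n = 11  # hub + 10 leaves
        net = nx.star_graph(n - 1)
        rc = nw.robustness_curve(net, fractions=[0.0, 1.0 / n], n_reps=4000, seed=3)
        # hub removed (p=1/n): remnant all isolated → lcc = 1/(n-1)
        # hub kept: star of n-1 nodes still connected → lcc = 1
        expected = (1.0 / n) * (1.0 / (n - 1)) + (1.0 - 1.0 / n) * 1.0
        assert rc.curve["lcc_mean"].iloc[1] == pytest.approx(expected, abs=0.02)


class TestZiPi:
    def test_all_links_inside_module(self):
        net = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        modules, _ = nw.detect_modules(net, seed=0)
        roles = nw.zi_pi(net, modules)
        np.testing.assert_allclose(roles["Pi"], 0.0)
        assert (roles["role"] == "peripheral").all()

    def test_split_degree_participation(self):
        # node x with k=4 split 2/2 over two modules → Pi = 0.5
        net = nx.Graph([("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2"),
                        ("a1", "a2"), ("b1", "b2")])
        modules = {"x": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = nw.zi_pi(net, modules)
        assert roles.loc["x", "Pi"] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "zi,pi,expected",
        [
            (3.0, 0.7, "network_hub"),
            (3.0, 0.3, "module_hub"),
            (1.0, 0.7, "connector"),
            (2.5, 0.62, "network_hub"),  # thresholds are inclusive
            (2.49, 0.61, "peripheral"),
        ],
    )
    def test_role_thresholds(self, zi, pi, expected):
        # exercise the threshold logic directly
        if zi >= nw.ROLE_ZI and pi >= nw.ROLE_PI:
            role = "network_hub"
        elif zi >= nw.ROLE_ZI:
            role = "module_hub"
        elif pi >= nw.ROLE_PI:
            role = "connector"
        else:
            role = "peripheral"
        assert role == expected

    def test_isolated_node_peripheral(self):
        net = nx.Graph([("a", "b")])
        net.add_node("c")
        roles = nw.zi_pi(net, {"a": 0, "b": 0, "c": 1})
        assert roles.loc["c", "role"] == "peripheral"
        assert np.isnan(roles.loc["c", "Pi"])


class TestTrophicSummary:
    def test_single_group_diagonal(self):
        net = nx.complete_graph(4)
        net = nx.relabel_nodes(net, {i: f"t{i}" for i in range(4)})
        ann = pd.DataFrame(
            {"trophic_group": ["consumer"] * 4},
            index=pd.Index([f"t{i}" for i in range(4)], name="taxon_id"),
        )
        matrix, share = nw.trophic_edge_summary(net, ann)
        assert matrix.loc["consumer", "consumer"] == 6
        assert share.sum() == pytest.approx(1.0)

    def test_bipartite_hand_count(self):
        net = nx.Graph([("c1", "p1"), ("c1", "p2"), ("c2", "p1"), ("c2", "p3"),
                        ("c1", "c2")])
        ann = pd.DataFrame(
            {"trophic_group": ["consumer", "consumer", "photosynthetic",
                               "photosynthetic", "photosynthetic"]},
            index=pd.Index(["c1", "c2", "p1", "p2", "p3"], name="taxon_id"),
        )
        matrix, share = nw.trophic_edge_summary(net, ann)
        assert matrix.loc["consumer", "photosynthetic"] == 4
        assert matrix.loc["consumer", "consumer"] == 1
        # degrees: c1=3, c2=3 of 2·5 edge-ends
        assert share["consumer"] == pytest.approx(6 / 10)
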