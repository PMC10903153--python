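"""Network construction, topology roles, and robustness tests."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sipaug.network import (
    EcoNetwork,
    build_network,
    classify_topology,
    detect_modules,
    equivalent_random_loss,
    keystone_ids,
    natural_connectivity,
    network_properties,
    robustness_random,
    robustness_targeted,
    zi_pi,
)

from conftest import make_table


def net_from_graph(g: nx.Graph) -> EcoNetwork:
    return EcoNetwork(graph=g, treatment="t", rho_threshold=0.6)


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------

class TestBuildNetwork:
    def _table(self, profiles: dict[str, list[float]], total=100_000):
        # columns are samples; a filler taxon pads every sample to the same
        # total so relative abundances stay proportional to the profiles
        n_samples = len(next(iter(profiles.values())))
        counts = {}
        for j in range(n_samples):
            col = [int(round(profiles[a][j] * 1000)) + 1 for a in profiles]
            counts[f"s{j}"] = col + [total - sum(col)]
        return make_table(counts, asv_ids=list(profiles) + ["filler"])

    def test_perfect_pair_connected_noise_pair_not(self):
        x = [1, 2, 3, 4, 5, 6]
        profiles = {
            "A": x,
            "B": [2 * v for v in x],           # exactly proportional: rho = 1
            "C": [5, 1, 4, 2, 6, 3],           # shuffled: low correlation
        }
        net = build_network(self._table(profiles), "t1", rho_threshold=0.95,
                            min_prevalence=0.0)
        edges = {frozenset(e) for e in net.graph.edges}
        assert frozenset(("A", "B")) in edges
        assert frozenset(("A", "C")) not in edges
        assert frozenset(("B", "C")) not in edges

    def test_threshold_above_one_empties_network(self):
        rng = np.random.default_rng(0)
        counts = {f"s{j}": rng.integers(1, 100, 10).tolist() for j in range(8)}
        net = build_network(make_table(counts), "t1", rho_threshold=1.01)
        assert net.graph.number_of_nodes() == 0

    def test_requires_five_samples(self):
        counts = {f"s{j}": [1, 2, 3] for j in range(4)}
        with pytest.raises(ValueError, match=">=5"):
            build_network(make_table(counts), "t1")

    def test_edges_match_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        # planted 2-block correlation structure over 20 ASVs x 12 samples
        z = rng.normal(size=(2, 12))
        profiles = np.empty((20, 12))
        for i in range(20):
            profiles[i] = 2 + z[i // 10] + 0.4 * rng.normal(size=12)
        counts = {
            f"s{j}": np.maximum(1, (profiles[:, j] * 100).astype(int)).tolist()
            for j in range(12)
        }
        table = make_table(counts)
        net = build_network(table, "t1", rho_threshold=0.6, min_prevalence=0.0)
        rel = table.relative_abundance().to_numpy()
        ids = table.asv_ids
        expected = set()
        for i in range(20):
            for j in range(i + 1, 20):
                rho = stats.pearsonr(rel[i], rel[j])[0]
                if abs(rho) > 0.6:
                    expected.add(frozenset((ids[i], ids[j])))
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected

    def test_signs_and_rho_stored(self):
        x = [1.0, 2, 3, 4, 5, 6]
        profiles = {"A": x, "B": x[::-1], "C": [10.0] * 6}
        table = self._table(profiles)
        with pytest.warns(UserWarning, match="constant"):
            net = build_network(table, "t1", rho_threshold=0.9, min_prevalence=0.0)
        (u, v, d), = net.graph.edges(data=True)
        assert {u, v} == {"A", "B"}
        assert d["sign"] == -1 and d["rho"] < -0.9


# ----------------------------------------------------------------------
# modules and roles
# ----------------------------------------------------------------------

class TestModulesAndRoles:
    def test_disconnected_cliques_form_two_modules(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
        net = net_from_graph(nx.relabel_nodes(g, str))
        modules, q = detect_modules(net)
        assert len(set(modules.values())) == 2
        assert len({modules[str(i)] for i in range(4)}) == 1
        assert len({modules[str(i)] for i in range(4, 9)}) == 1
        assert q > 0

    def test_single_clique_one_module_zero_q(self):
        net = net_from_graph(nx.relabel_nodes(nx.complete_graph(5), str))
        modules, q = detect_modules(net)
        assert len(set(modules.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_all_within_module_edges_give_pi_zero(self):
        g = nx.complete_graph(4)
        net = net_from_graph(nx.relabel_nodes(g, str))
        modules, _ = detect_modules(net)
        records = zi_pi(net, modules)
        assert np.allclose(records["pi"], 0.0)

    def test_pi_closed_form_for_2_2_split(self):
        # node X with degree 4 split evenly across two modules
        g = nx.Graph()
        g.add_edges_from([("X", "a1"), ("X", "a2"), ("X", "b1"), ("X", "b2")])
        g.add_edges_from([("a1", "a2"), ("b1", "b2")])
        modules = {"X": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        records = zi_pi(net_from_graph(g), modules)
        assert records.loc["X", "pi"] == pytest.approx(0.5)

    def test_zi_matches_direct_mean_sd_oracle_for_star_module(self):
        g = nx.star_graph(9)  # hub 0 + 9 leaves, one module
        g = nx.relabel_nodes(g, str)
        modules = {n: 0 for n in g.nodes}
        records = zi_pi(net_from_graph(g), modules)
        degrees = [9] + [1] * 9
        oracle = (9 - np.mean(degrees)) / np.std(degrees)
        assert records.loc["0", "zi"] == pytest.approx(oracle, rel=1e-12)
        # leaves share the module: sd > 0, so their Zi is the oracle too
        leaf_oracle = (1 - np.mean(degrees)) / np.std(degrees)
        assert records.loc["3", "zi"] == pytest.approx(leaf_oracle, rel=1e-12)

    def test_zero_sd_module_gives_zi_zero(self):
        net = net_from_graph(nx.relabel_nodes(nx.complete_graph(4), str))
        records = zi_pi(net, {n: 0 for n in net.graph.nodes})
        assert np.allclose(records["zi"], 0.0)

    @pytest.mark.parametrize(
        "zi,pi,role",
        [
            (2.6, 0.3, "module_hub"),
            (3.0, 0.7, "network_hub"),
            (2.5, 0.62, "peripheral"),   # boundaries belong to <=
            (2.0, 0.7, "connector"),
            (2.5, 0.63, "connector"),
            (2.51, 0.62, "module_hub"),
            (-1.0, 0.0, "peripheral"),
        ],
    )
    def test_role_thresholds_exact_semantics(self, zi, pi, role):
        records = pd.DataFrame({"zi": [zi], "pi": [pi], "degree": [5]}, index=["n"])
        out = classify_topology(records)
        assert out.loc["n", "role"] == role
        assert out.loc["n", "keystone"] == (role != "peripheral")

    def test_keystone_removal_order(self):
        records = pd.DataFrame(
            {
                "zi": [3.0, 3.0, 1.0, 1.0],
                "pi": [0.1, 0.1, 0.7, 0.7],
                "degree": [5, 9, 4, 4],
            },
            index=["mh_small", "mh_big", "conn_a", "conn_b"],
        )
        order = keystone_ids(classify_topology(records))
        assert order == ["mh_big", "mh_small", "conn_a", "conn_b"]


# ----------------------------------------------------------------------
# natural connectivity and removal
# ----------------------------------------------------------------------

class TestNaturalConnectivity:
    def test_edgeless_graph_is_zero(self):
        g = nx.empty_graph(7)
        assert natural_connectivity(net_from_graph(g)) == pytest.approx(0.0)

    def test_triangle_closed_form(self):
        lam = natural_connectivity(net_from_graph(nx.complete_graph(3)))
        assert lam == pytest.approx(math.log((math.e**2 + 2 * math.e**-1) / 3), abs=1e-12)

    def test_path_closed_form(self):
        lam = natural_connectivity(net_from_graph(nx.path_graph(3)))
        s = math.sqrt(2)
        assert lam == pytest.approx(
            math.log((math.e**s + 1 + math.e**-s) / 3), abs=1e-12
        )

    def test_adding_an_edge_never_decreases_it(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1e6)))
            lam = natural_connectivity(net_from_graph(g))
            for u in range(12):
                for v in range(u + 1, 12):
                    if g.has_edge(u, v):
                        continue
                    g2 = g.copy()
                    g2.add_edge(u, v)
                    assert natural_connectivity(net_from_graph(g2)) >= lam - 1e-12


def star_random_curve_exact(n_leaves: int = 9) -> np.ndarray:
    """Exact mean natural-connectivity curve for uniform removal from a star.

    A uniform removal sequence of length m is a uniform m-subset.  With the
    hub removed the graph is edgeless (0); with the hub alive and l leaves
    left the eigenvalues are +/-sqrt(l) and zeros.
    """
    n = n_leaves + 1
    out = np.empty(n + 1)
    for m in range(n + 1):
        p_hub_gone = m / n
        l = n_leaves - m  # leaves left when the hub survives
        if l >= 0 and n - m > 0:
            lam_alive = math.log(
                (math.exp(math.sqrt(l)) + math.exp(-math.sqrt(l)) + (l - 1)) / (n - m)
            ) if l > 0 else 0.0
        else:
            lam_alive = 0.0
        out[m] = (1 - p_hub_gone) * lam_alive
    return out


class TestRemoval:
    def test_removing_zero_nodes_changes_nothing(self):
        net = net_from_graph(nx.karate_club_graph())
        lam = natural_connectivity(net)
        curve = robustness_targeted(net, [])
        assert curve.mean[0] == pytest.approx(lam)
        assert len(curve.mean) == 1

    def test_targeted_hub_loss_beats_mean_random_loss_on_star(self):
        net = net_from_graph(nx.star_graph(9))
        lam0 = natural_connectivity(net)
        targeted_drop = lam0 - robustness_targeted(net, [0]).mean[-1]
        exact = star_random_curve_exact()
        mean_random_drop_1 = lam0 - exact[1]
        assert targeted_drop > mean_random_drop_1

    def test_random_curve_matches_exact_enumeration_on_star(self):
        net = net_from_graph(nx.star_graph(9))
        curve = robustness_random(net, max_removed=10, n_reps=4000, seed=0)
        exact = star_random_curve_exact()
        np.testing.assert_allclose(curve.mean, exact, atol=0.03)

    def test_random_curve_monotone_nonincreasing_in_expectation(self):
        net = net_from_graph(nx.connected_watts_strogatz_graph(20, 4, 0.2, seed=1))
        curve = robustness_random(net, max_removed=10, n_reps=200, seed=2)
        assert np.all(np.diff(curve.mean) < 0.05)

    def test_equivalent_loss_trivial_and_star_enumeration(self):
        net = net_from_graph(nx.star_graph(9))
        assert equivalent_random_loss(net, [], n_reps=10, seed=0) == (0, 0.0)
        n_eq, pct = equivalent_random_loss(net, [0], n_reps=500, seed=0)
        # exact: the mean random curve first reaches 0 (the targeted level)
        # at m = 9, when at most one node (hence no edge) can remain
        exact = star_random_curve_exact()
        lam_t = 0.0
        expected_n = int(np.flatnonzero(exact <= lam_t + 1e-12)[0])
        assert n_eq == expected_n == 9
        assert pct == pytest.approx(100.0)
        assert n_eq >= 1  # targeted drop exceeds mean random drop at m=1

    def test_zero_connectivity_network_raises(self):
        net = net_from_graph(nx.empty_graph(4))
        with pytest.raises(ValueError, match="natural connectivity"):
            equivalent_random_loss(net, ["0"], n_reps=10, seed=0)


def test_network_properties_summary():
    g = nx.relabel_nodes(nx.disjoint_union(nx.complete_graph(4), nx.path_graph(3)), str)
    net = net_from_graph(g)
    nx.set_edge_attributes(net.graph, 1, "sign")
    props = network_properties(net)
    assert props["n_nodes"] == 7 and props["n_edges"] == 8
    assert props["average_degree"] == pytest.approx(16 / 7)
    assert props["pct_positive_edges"] == 100.0
    # average path distance is taken over the largest component (the clique)
    assert props["average_path_distance"] == pytest.approx(1.0)
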