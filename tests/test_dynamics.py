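"""Module detection, topology metrics and module completeness."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from sludgenet import (clustering_coefficient, coexclusion_proportion,
                       detect_modules, extract_timepoint_networks, modularity,
                       module_completeness, occurrence_matrix, topology_table,
                       CountMatrix)
from sludgenet.dynamics import TimepointNetwork
from sludgenet.io import ConsistencyError
from sludgenet.metaweb import build_metaweb, filter_by_occurrence

from conftest import metaweb_from_edges


def clique_edges(nodes):
    return list(combinations(nodes, 2))


def brute_force_transitivity(graph: nx.Graph) -> float:
    """Independent triangle/triple counter by explicit enumeration."""
    triangles = 0
    triples = 0
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        for a, b in combinations(nbrs, 2):
            triples += 1
            triangles += graph.has_edge(a, b)
    if triples == 0:
        return float("nan")
    return triangles / triples  # each triangle counted once per apex = 3x


class TestDetectModules:
    def test_disjoint_cliques_found_exactly(self):
        web = metaweb_from_edges(co=clique_edges("abcde") + clique_edges("vwxyz"))
        part = detect_modules(web)
        assert part.n_modules == 2
        members = part.module_members()
        assert sorted(map(sorted, members.values())) == [list("abcde"), list("vwxyz")]

    def test_complete_graph_single_module(self):
        web = metaweb_from_edges(co=clique_edges("abcdef"))
        part = detect_modules(web)
        assert part.n_modules == 1
        assert part.modularity == pytest.approx(0.0)

    def test_planted_partition_recovery(self):
        """Two 30-node blocks (p_in=0.3, p_out=0.01) recovered with ARI >= 0.9."""
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            names = [f"n{i:02d}" for i in range(60)]
            co = []
            for i, j in combinations(range(60), 2):
                p = 0.3 if (i < 30) == (j < 30) else 0.01
                if rng.random() < p:
                    co.append((names[i], names[j]))
            web = metaweb_from_edges(co=co)
            part = detect_modules(web)
            truth = [int(int(n[1:]) >= 30) for n in web.nodes]
            found = [part.labels[n] for n in web.nodes]
            aris.append(adjusted_rand_score(truth, found))
        assert np.mean(aris) >= 0.9

    def test_isolated_nodes_get_singletons(self):
        web = metaweb_from_edges(co=[("a", "b")], ex=[("c", "d")])
        part = detect_modules(web)
        assert part.labels["c"] != part.labels["d"]
        assert len({part.labels["a"], part.labels["b"]}) == 1


class TestModularity:
    def test_single_module_partition_is_zero(self):
        g = nx.gnp_random_graph(12, 0.4, seed=5)
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        g = nx.Graph(clique_edges("abc") + clique_edges("xyz"))
        part = {n: 0 if n in "abc" else 1 for n in g.nodes}
        assert modularity(g, part) == pytest.approx(0.5)

    def test_edgeless_graph_undefined(self):
        g = nx.empty_graph(4)
        assert np.isnan(modularity(g, {n: 0 for n in g.nodes}))

    def test_missing_node_raises(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ConsistencyError):
            modularity(g, {"a": 0})


class TestClustering:
    @pytest.mark.parametrize("graph,expected", [
        (nx.complete_graph(5), 1.0),
        (nx.star_graph(5), 0.0),
    ])
    def test_hand_values(self, graph, expected):
        assert clustering_coefficient(graph) == pytest.approx(expected)

    def test_no_triples_undefined(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert np.isnan(clustering_coefficient(g))

    def test_matches_brute_force_enumeration(self):
        # triangle A-B-C with pendant D on C, plus random graphs
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        assert clustering_coefficient(g) == pytest.approx(brute_force_transitivity(g))
        for seed in range(5):
            g = nx.gnp_random_graph(15, 0.3, seed=seed)
            assert clustering_coefficient(g) == pytest.approx(
                brute_force_transitivity(g), nan_ok=True)


class TestCoexclusionProportion:
    def make_tp(self, n_co, n_ex):
        nodes = [f"n{i}" for i in range(max(2 * (n_co + n_ex), 2))]
        co = [(nodes[2 * i], nodes[2 * i + 1]) for i in range(n_co)]
        ex = [(nodes[2 * (n_co + i)], nodes[2 * (n_co + i) + 1]) for i in range(n_ex)]
        return TimepointNetwork("s", nodes, co, ex)

    @pytest.mark.parametrize("n_co,n_ex,expected", [
        (3, 0, 0.0), (0, 4, 1.0), (9, 3, 0.25),
    ])
    def test_values(self, n_co, n_ex, expected):
        assert coexclusion_proportion(self.make_tp(n_co, n_ex)) == pytest.approx(expected)

    def test_no_edges_undefined(self):
        assert np.isnan(coexclusion_proportion(self.make_tp(0, 0)))


class TestModuleCompleteness:
    def build(self, presence):
        n, N = presence.shape
        cm = CountMatrix(
            asv_ids=[f"a{i}" for i in range(n)],
            sample_ids=[f"s{j}" for j in range(N)],
            counts=presence.astype(int),
            sample_map={f"s{j}": (j + 1, 1) for j in range(N)},
        )
        return occurrence_matrix(cm)

    def test_proportions(self):
        from sludgenet.dynamics import ModulePartition

        pres = np.array([[1, 1, 0], [1, 0, 0], [1, 1, 0], [1, 0, 0], [1, 1, 0]])
        occ = self.build(pres)
        part = ModulePartition(labels={f"a{i}": 0 for i in range(5)}, modularity=0.0)
        comp = module_completeness(part, occ)
        assert list(comp[0]) == pytest.approx([1.0, 0.6, 0.0])

    def test_monotone_in_presence(self):
        from sludgenet.dynamics import ModulePartition

        rng = np.random.default_rng(0)
        pres = rng.random((10, 6)) < 0.5
        occ = self.build(pres)
        part = ModulePartition(
            labels={f"a{i}": i % 3 for i in range(10)}, modularity=0.0)
        base = module_completeness(part, occ)
        added = pres.copy()
        added[3, :] = True  # one node becomes present everywhere
        comp2 = module_completeness(part, self.build(added))
        assert (comp2.to_numpy() >= base.to_numpy() - 1e-12).all()


class TestTimepointNetworks:
    def test_full_sample_reproduces_metaweb(self):
        web = metaweb_from_edges(co=clique_edges("abcd"), ex=[("a", "e"), ("b", "e")])
        pres = np.ones((5, 1), dtype=bool)
        cm = CountMatrix([*"abcde"], ["s0"], pres.astype(int), {"s0": (1, 1)})
        occ = occurrence_matrix(cm)
        (tp,) = extract_timepoint_networks(web, occ)
        assert len(tp.cooccurrence_edges) == len(web.cooccurrence)
        assert len(tp.coexclusion_edges) == len(web.coexclusion)

    def test_empty_sample_undefined_metrics(self):
        web = metaweb_from_edges(co=clique_edges("abcd"))
        cm = CountMatrix([*"abcd"], ["s0"], np.zeros((4, 1), dtype=int), {"s0": (1, 1)})
        (tp,) = extract_timepoint_networks(web, occurrence_matrix(cm))
        assert tp.nodes == []
        assert all(np.isnan(v) for v in tp.metrics.values())

    def test_induced_edges_match_double_loop(self):
        rng = np.random.default_rng(9)
        names = [f"n{i:02d}" for i in range(20)]
        co = [(a, b) for a, b in combinations(names, 2) if rng.random() < 0.2]
        ex = [(a, b) for a, b in combinations(names, 2) if rng.random() < 0.05]
        ex = [e for e in ex if e not in set(co)]
        web = metaweb_from_edges(co=co, ex=ex)
        pres = rng.random((len(web.nodes), 4)) < 0.6
        cm = CountMatrix(web.nodes, [f"s{j}" for j in range(4)],
                         pres.astype(int),
                         {f"s{j}": (j + 1, 1) for j in range(4)})
        occ = occurrence_matrix(cm)
        nets = extract_timepoint_networks(web, occ)
        for s, tp in enumerate(nets):
            present = {web.nodes[i] for i in np.flatnonzero(pres[:, s])}
            expect_co = {tuple(sorted(e)) for e in web.cooccurrence
                         if e[0] in present and e[1] in present}
            assert {tuple(sorted(e)) for e in tp.cooccurrence_edges} == expect_co

    def test_seasonal_completeness_tracks_temperature(self, seasonal_run):
        res = seasonal_run
        filt = filter_by_occurrence(res.counts)
        occ = occurrence_matrix(filt)
        web = build_metaweb(occ)
        part = detect_modules(web)
        comp = module_completeness(part, occ)
        temps = np.array([res.truth["temperature"][res.counts.sample_map[s][0] - 1]
                          for s in occ.sample_ids])
        sizes = {m: members for m, members in part.module_members().items()}
        top2 = sorted(sizes, key=lambda m: len(sizes[m]), reverse=True)[:2]
        rhos = sorted(stats.spearmanr(comp[m], temps)[0] for m in top2)
        assert rhos[0] <= -0.6 and rhos[1] >= 0.6
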