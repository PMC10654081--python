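import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pitmud import CommunityTable, to_relative
from pitmud._errors import DataError, ValidationError
from pitmud import network as net
from pitmud.table import RANKS


def triangle_pair():
    g = nx.Graph()
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        g.add_edge(a, b, weight=1.0, sign="positive", rho=1.0, p_value=0.0)
    return g


class TestCorrelationScreen:
    def test_matches_brute_force_double_loop(self, rng):
        """Retained set equals an independent per-pair rank screen
        (Pearson on average ranks, exact t p-value)."""
        table = to_relative(CommunityTable(pd.DataFrame(
            rng.lognormal(0, 1, (20, 30)),
            index=[f"t{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(30)])))
        edges = net.correlation_screen(table, rho_threshold=0.3, alpha=0.05)
        got = {(r.taxon_u, r.taxon_v) for r in edges.itertuples()}
        x = table.matrix()
        n = x.shape[1]
        expected = set()
        for i, j in itertools.combinations(range(20), 2):
            ri = sps.rankdata(x[i])
            rj = sps.rankdata(x[j])
            rho = np.corrcoef(ri, rj)[0, 1]
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = 2 * sps.t.sf(abs(t), n - 2)
            if abs(rho) > 0.3 and p < 0.05:
                expected.add((f"t{i}", f"t{j}"))
        assert got == expected

    def test_threshold_is_strict_on_rho(self):
        # two taxa tracking each other except one swap: rho just below
        # threshold with tiny p must be rejected; a clean monotone pair
        # with rho above the threshold is retained
        a = np.arange(20.0)
        b = a.copy(); b[0], b[19] = b[19], b[0]   # rho approx 0.45
        c = a + 0.1
        table = CommunityTable(pd.DataFrame(
            {"s%d" % i: [a[i], b[i], c[i]] for i in range(20)},
            index=["ta", "tb", "tc"]))
        edges = net.correlation_screen(table, rho_threshold=0.7, alpha=0.01)
        kept = {frozenset((r.taxon_u, r.taxon_v)) for r in edges.itertuples()}
        assert frozenset(("ta", "tc")) in kept
        assert frozenset(("ta", "tb")) not in kept

    def test_constant_taxon_skipped(self, rng):
        table = CommunityTable(pd.DataFrame(
            np.vstack([np.full(10, 5.0), rng.lognormal(0, 1, (3, 10))]),
            index=["const", "a", "b", "c"],
            columns=[f"s{j}" for j in range(10)]))
        edges = net.correlation_screen(table, 0.0, 1.0)
        touched = set(edges["taxon_u"]) | set(edges["taxon_v"])
        assert "const" not in touched

    def test_retained_set_invariant_to_orderings(self, rng):
        df = pd.DataFrame(rng.lognormal(0, 1, (10, 20)),
                          index=[f"t{i}" for i in range(10)],
                          columns=[f"s{j}" for j in range(20)])
        rel1 = to_relative(CommunityTable(df))
        rel2 = to_relative(CommunityTable(
            df.iloc[::-1, ::-1]))  # reversed taxa and samples
        e1 = {frozenset((r.taxon_u, r.taxon_v))
              for r in net.correlation_screen(rel1, 0.3, 0.1).itertuples()}
        e2 = {frozenset((r.taxon_u, r.taxon_v))
              for r in net.correlation_screen(rel2, 0.3, 0.1).itertuples()}
        assert e1 == e2

    def test_fdr_toggle_only_shrinks_edge_set(self, rng):
        table = CommunityTable(pd.DataFrame(
            rng.lognormal(0, 1, (12, 20)),
            index=[f"t{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(20)]))
        raw = net.correlation_screen(table, 0.2, 0.05)
        adj = net.correlation_screen(table, 0.2, 0.05, fdr=True)
        raw_pairs = {frozenset((r.taxon_u, r.taxon_v)) for r in raw.itertuples()}
        adj_pairs = {frozenset((r.taxon_u, r.taxon_v)) for r in adj.itertuples()}
        assert adj_pairs <= raw_pairs

    def test_too_few_samples_rejected(self, rng):
        table = to_relative(CommunityTable(pd.DataFrame(
            rng.lognormal(0, 1, (4, 4)), index=list("abcd"),
            columns=[f"s{j}" for j in range(4)])))
        with pytest.raises(DataError):
            net.correlation_screen(table)


class TestTopology:
    def test_two_triangles_modularity_half(self):
        # hand oracle: Q = sum_c (e_c/m - (d_c/2m)^2) = 2*(3/6 - (6/12)^2) = 0.5
        _, q = net.best_louvain_partition(triangle_pair(), seed=1)
        assert q == pytest.approx(0.5)

    def test_complete_graph_density_and_degree(self):
        k5 = nx.complete_graph(5)
        nx.set_edge_attributes(k5, 1.0, "weight")
        nx.set_edge_attributes(k5, "positive", "sign")
        rep = net.topology(k5, seed=0)
        assert rep.density == pytest.approx(1.0)
        assert rep.average_degree == pytest.approx(4.0)
        assert rep.n_connected_components == 1

    def test_neg_pos_ratio_percentage(self):
        g = nx.Graph()
        for i in range(10):
            g.add_edge(f"p{i}", f"q{i}", weight=1.0, sign="positive")
        for i in range(5):
            g.add_edge(f"n{i}", f"m{i}", weight=1.0, sign="negative")
        assert net.topology(g, seed=0).neg_pos_ratio == pytest.approx(50.0)

    def test_louvain_beats_trivial_partition(self, rng):
        g = nx.erdos_renyi_graph(30, 0.15, seed=4)
        nx.set_edge_attributes(g, 1.0, "weight")
        _, q = net.best_louvain_partition(g, seed=0)
        assert q >= 0.0  # trivial one-community partition has Q = 0

    @pytest.mark.parametrize("m,flag", [(0.515, True), (0.265, False),
                                        (0.4, False)])
    def test_modular_structure_flag(self, m, flag):
        assert net.modular_structure_flag(m) is flag


class TestFocalClassEdges:
    def _taxonomy(self, mapping):
        df = pd.DataFrame({r: pd.Series(mapping) for r in RANKS})
        return df

    def test_all_focal_no_inter(self):
        g = triangle_pair()
        tax = self._taxonomy({n: "Clostridia" for n in g.nodes})
        out = net.focal_class_edges(g, tax, "Clostridia")
        assert out["inter_positive"] == 0 and out["inter_negative"] == 0
        assert out["intra_positive"] == 6

    def test_star_hub_decomposition(self):
        g = nx.Graph()
        for leaf in "abcd":
            g.add_edge("hub", leaf, weight=1.0, sign="positive")
        tax = self._taxonomy({"hub": "Clostridia", "a": "x", "b": "x",
                              "c": "y", "d": "y"})
        out = net.focal_class_edges(g, tax, "Clostridia")
        assert out == {"intra_positive": 0, "intra_negative": 0,
                       "inter_positive": 4, "inter_negative": 0}

    def test_matches_brute_force_loop(self, rng):
        g = nx.erdos_renyi_graph(15, 0.3, seed=7)
        classes = {n: rng.choice(["F", "G", "H"]) for n in g.nodes}
        for u, v in g.edges:
            g[u][v]["sign"] = rng.choice(["positive", "negative"])
            g[u][v]["weight"] = 1.0
        tax = self._taxonomy(classes)
        out = net.focal_class_edges(g, tax, "F")
        expected = {"intra_positive": 0, "intra_negative": 0,
                    "inter_positive": 0, "inter_negative": 0}
        for u, v, d in g.edges(data=True):
            fu, fv = classes[u] == "F", classes[v] == "F"
            if not (fu or fv):
                continue
            kind = "intra" if fu and fv else "inter"
            expected[f"{kind}_{'positive' if d['sign'] == 'positive' else 'negative'}"] += 1
        assert out == expected

    def test_unknown_class_rejected(self):
        g = triangle_pair()
        tax = self._taxonomy({n: "x" for n in g.nodes})
        with pytest.raises(ValidationError):
            net.focal_class_edges(g, tax, "nope")


class TestRobustness:
    def test_zero_removal_keeps_everything(self):
        rc = net.robustness(nx.complete_graph(10), n_reps=5, seed=0)
        assert rc.mean_remaining[0] == 1.0

    def test_complete_graph_closed_form(self):
        # removals never isolate survivors until < 2 remain, so the curve
        # is deterministic: remaining = (n - round(qn))/n, or 0 if <= 1
        n = 10
        rc = net.robustness(nx.complete_graph(n), n_reps=10, seed=1)
        for q, mean, sd in zip(rc.removal_fractions, rc.mean_remaining,
                               rc.sd_remaining):
            left = n - int(round(q * n))
            expected = left / n if left >= 2 else 0.0
            assert mean == pytest.approx(expected)
            assert sd == pytest.approx(0.0, abs=1e-12)

    def test_star_collapses_below_complete_graph(self):
        star = nx.star_graph(9)    # 10 nodes
        comp = nx.complete_graph(10)
        rs = net.robustness(star, n_reps=200, seed=2)
        rk = net.robustness(comp, n_reps=200, seed=2)
        # compare where at least one node is actually removed (q = 0.05
        # of 10 nodes rounds to zero removals) and the complete graph has
        # not yet collapsed
        interior = (rk.removal_fractions >= 0.1) & (rk.mean_remaining > 0)
        assert (rs.mean_remaining[interior] < rk.mean_remaining[interior]).all()
        assert rs.robustness_score < rk.robustness_score

    def test_curve_monotone_and_bounded(self, rng):
        g = nx.erdos_renyi_graph(25, 0.2, seed=3)
        rc = net.robustness(g, n_reps=30, seed=4)
        assert ((rc.mean_remaining >= 0) & (rc.mean_remaining <= 1)).all()
        slack = 2 * np.maximum(rc.sd_remaining[1:], 1e-12)
        assert (np.diff(rc.mean_remaining) <= slack).all()
        assert 0.0 <= rc.robustness_score <= 1.0

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            net.robustness(nx.complete_graph(8), step=0.3, n_reps=5, seed=0)
        with pytest.raises(ValidationError):
            net.robustness(nx.complete_graph(8), n_reps=1, seed=0)
        with pytest.raises(DataError):
            net.robustness(nx.complete_graph(3), n_reps=5, seed=0)


class TestVulnerability:
    def test_complete_graph_symmetric_small(self):
        v = net.vulnerability(nx.complete_graph(4))
        # removing any node of K4 leaves K3: E drops 1 -> (6-3)/6 pairs..
        # E(K_n) = 1; E_i over remaining pairs also 1 computed on K3, but
        # global_efficiency averages over n(n-1) ordered pairs of the
        # REMAINING graph, so the drop is 0 -> vulnerability 0
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_path_graph_hand_enumeration(self):
        # P4 0-1-2-3: E = (3*1 + 2*0.5 + 1/3)/6 = 0.72222
        # removing node 1: {0},{2-3}: E_i = 1/3; drop = (E-E_i)/E
        e = (3 * 1 + 2 * 0.5 + 1 / 3) / 6
        e_i = 1 / 3
        assert net.vulnerability(nx.path_graph(4)) == pytest.approx(
            (e - e_i) / e)

    def test_matches_scratch_recomputation_after_edge_add(self, rng):
        g = nx.erdos_renyi_graph(12, 0.25, seed=8)
        g.add_edge(0, 11)
        expected = -np.inf
        e = nx.global_efficiency(g)
        for node in g.nodes:
            h = g.copy(); h.remove_node(node)
            expected = max(expected, (e - nx.global_efficiency(h)) / e)
        assert net.vulnerability(g) == pytest.approx(expected)

    def test_small_graph_rejected(self):
        with pytest.raises(DataError):
            net.vulnerability(nx.path_graph(2))


class TestBuildNetwork:
    def test_self_loops_dropped_and_weights_abs(self):
        edges = pd.DataFrame({
            "taxon_u": ["a", "a"], "taxon_v": ["a", "b"],
            "rho": [0.9, -0.8], "p_value": [0.001, 0.001],
            "sign": ["positive", "negative"]})
        g = net.build_network(edges)
        assert list(g.edges) == [("a", "b")]
        assert g["a"]["b"]["weight"] == pytest.approx(0.8)
        assert g["a"]["b"]["sign"] == "negative"
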