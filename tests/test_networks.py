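"""Correlation statistics, network construction, cliques, universal edges, ORA."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isomirnet.networks import (
    NetworkError,
    PipelineThresholds,
    RegulatoryNetwork,
    bh_adjust,
    build_interaction_network,
    find_modules,
    isomir_coexpression_graph,
    ita,
    module_representatives,
    ora_enrichment,
    spearman_rho,
    universal_interactions,
)
from isomirnet.targetome import Targetome


def bh_oracle(pvalues):
    """Step-up brute force: sort, p*(m/i), cumulative min from the largest."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top
        running = min(running, p[idx] * m / i)
        adjusted[idx] = running
    return adjusted


def spearman_oracle(x, y):
    """Mid-rank then Pearson, written independently of scipy.spearmanr."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_perfect_anti_monotone(self):
        rho, p = spearman_rho([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(NetworkError):
            spearman_rho([1, 2, 3], [3, 3, 3])

    def test_tied_vectors_match_midrank_pearson_oracle(self, rng):
        for _ in range(25):
            x = rng.integers(0, 6, size=20).astype(float)
            y = rng.integers(0, 6, size=20).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        # n=3 monotone: |rho|=1 is reached by exactly 2 of 6 permutations
        _, p = spearman_rho([1, 2, 3], [10, 20, 30], method="exact")
        assert p == pytest.approx(2 / 6)

    def test_exact_limited_to_small_n(self):
        with pytest.raises(NetworkError):
            spearman_rho(list(range(12)), list(range(12)), method="exact")


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ratio_collapse(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_two_values(self):
        assert bh_adjust([0.05, 0.5]) == pytest.approx([0.10, 0.5])

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(NetworkError):
            bh_adjust([0.5, 1.5])


def _expr(rows: dict, samples=None) -> pd.DataFrame:
    frame = pd.DataFrame(rows).T
    frame.columns = samples or [f"s{i}" for i in range(frame.shape[1])]
    return frame


def _targetomes(mapping: dict) -> dict:
    return {n: Targetome(n, {g: "both" for g in genes}) for n, genes in mapping.items()}


class TestInteractionNetwork:
    def test_single_anticorrelated_pair_is_an_edge(self, rng):
        x = np.arange(20.0) + rng.normal(0, 0.01, 20)
        iso = _expr({"i—0": x})
        gene = _expr({"G": 50.0 - 2 * x + rng.normal(0, 0.1, 20)})
        net = build_interaction_network(iso, gene, _targetomes({"i—0": {"G"}}))
        assert net.edges.loc[0, "significant"]
        assert net.graph.has_edge("i—0", "G")

    def test_weak_rho_fails_gate_despite_tiny_p(self, rng):
        # rho about -0.2 but n large -> small p; the rho gate must still block
        n = 4000
        x = rng.normal(size=n)
        y = -0.2 * x + rng.normal(size=n)
        iso = _expr({"i—0": x})
        gene = _expr({"G": y - y.min()})
        net = build_interaction_network(iso, gene, _targetomes({"i—0": {"G"}}))
        row = net.edges.iloc[0]
        assert row["fdr_global"] < 1e-6 and row["rho"] > -0.3
        assert not row["significant"]

    def test_fdr_local_equals_bh_of_sublist(self, rng):
        x = rng.normal(size=30)
        genes = {f"G{j}": rng.normal(size=30) + 5 for j in range(6)}
        iso = _expr({"i—0": x + 5})
        gene = _expr(genes)
        net = build_interaction_network(iso, gene, _targetomes({"i—0": set(genes)}))
        sub = net.edges[net.edges["isomir"] == "i—0"]
        assert np.allclose(sub["fdr_local"], bh_oracle(sub["p_raw"].to_numpy()))

    def test_shared_sample_minimum(self):
        iso = _expr({"i—0": [1.0, 2.0]})
        gene = _expr({"G": [2.0, 1.0]})
        with pytest.raises(NetworkError):
            build_interaction_network(iso, gene, _targetomes({"i—0": {"G"}}))

    def test_tightening_thresholds_never_adds_edges(self, rng):
        iso = _expr({f"i{k}—0": rng.normal(size=40) for k in range(4)})
        gene = _expr({f"G{j}": rng.normal(size=40) + 8 for j in range(25)})
        iso += 8
        tg = _targetomes({n: {f"G{j}" for j in range(25)} for n in iso.index})
        loose = build_interaction_network(iso, gene, tg, PipelineThresholds())
        tight = build_interaction_network(
            iso, gene, tg, PipelineThresholds(rho_max=-0.5, fdr_max=0.01)
        )
        loose_edges = set(map(tuple, loose.edges[loose.edges["significant"]][["isomir", "gene"]].to_numpy()))
        tight_edges = set(map(tuple, tight.edges[tight.edges["significant"]][["isomir", "gene"]].to_numpy()))
        assert tight_edges <= loose_edges


class TestIta:
    def test_empty_network_reports_zeros(self, rng):
        iso = _expr({"i—0": rng.normal(size=10) + 5})
        gene = _expr({"G": rng.normal(size=10) + 5})
        net = build_interaction_network(iso, gene, _targetomes({"i—0": {"G"}}),
                                        PipelineThresholds(fdr_max=1e-9))
        assert ita(net) == {"i—0": 0}

    def test_out_degree_and_handshake(self, rng):
        x = np.arange(30.0)
        iso = _expr({"i—0": x})
        gene = _expr({f"G{j}": 99.0 - x + rng.normal(0, 0.1, 30) for j in range(3)})
        net = build_interaction_network(iso, gene, _targetomes({"i—0": {"G0", "G1", "G2"}}))
        counts = ita(net)
        assert counts["i—0"] == 3
        assert sum(counts.values()) == net.graph.number_of_edges()


class TestCoexpressionModules:
    def test_strict_threshold_boundary(self):
        # second profile has Spearman exactly 0.5 with the first (no edge),
        # third has 0.6 (edge), fourth is its negative (edge via |rho|)
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        half = [2.0, 4.0, 1.0, 3.0, 5.0]   # sum d^2 = 10 -> rho = 0.5
        point6 = [2.0, 1.0, 5.0, 3.0, 4.0]  # sum d^2 = 8 -> rho = 0.6
        expr = _expr({"a": base, "b": half, "c": point6, "d": [-v for v in point6]})
        graph = isomir_coexpression_graph(expr)
        assert not graph.has_edge("a", "b")
        assert graph.has_edge("a", "c")
        assert graph.has_edge("a", "d")

    def test_adjacency_matches_pairwise_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 25)),
                            index=list("abcde"))
        graph = isomir_coexpression_graph(expr, 0.3)
        for u, v in itertools.combinations(expr.index, 2):
            rho = stats.spearmanr(expr.loc[u], expr.loc[v]).statistic
            assert graph.has_edge(u, v) == (abs(rho) > 0.3)

    def test_triangle_plus_pendant(self):
        graph = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        assert set(find_modules(graph)) == {frozenset("ABC"), frozenset("CD")}

    def test_complete_graph_single_clique(self):
        graph = nx.complete_graph(4)
        assert find_modules(graph) == [frozenset(range(4))]

    def test_isolated_nodes_are_singletons(self):
        graph = nx.empty_graph(3)
        assert set(find_modules(graph)) == {frozenset({0}), frozenset({1}), frozenset({2})}

    def test_cliques_match_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 11))
            graph = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            found = set(find_modules(graph))
            nodes = list(graph.nodes)
            maximal = set()
            for r in range(1, n + 1):
                for subset in itertools.combinations(nodes, r):
                    s = set(subset)
                    if all(graph.has_edge(u, v) for u, v in itertools.combinations(s, 2)):
                        if not any(
                            all(graph.has_edge(w, u) for u in s)
                            for w in nodes if w not in s
                        ):
                            maximal.add(frozenset(s))
            assert found == maximal

    def test_representatives_highest_median_and_ties(self):
        expr = _expr({"a": [5.0] * 5, "b": [9.0] * 5, "c": [9.0] * 5})
        assert module_representatives([frozenset({"a", "b"})], expr) == {"b"}
        assert module_representatives([frozenset({"b", "c"})], expr) == {"b"}

    def test_overlapping_cliques_share_representative(self):
        expr = _expr({"a": [1.0] * 5, "b": [9.0] * 5, "c": [2.0] * 5})
        reps = module_representatives([frozenset({"a", "b"}), frozenset({"b", "c"})], expr)
        assert reps == {"b"}

    def test_member_without_expression_rejected(self):
        expr = _expr({"a": [1.0] * 5})
        with pytest.raises(NetworkError):
            module_representatives([frozenset({"a", "z"})], expr)


def _fake_network(cohort, sig_pairs):
    edges = pd.DataFrame(
        [
            {"isomir": i, "gene": g, "rho": -0.5, "p_raw": 1e-4,
             "fdr_global": 1e-3, "fdr_local": 1e-3, "significant": True}
            for i, g in sig_pairs
        ],
        columns=["isomir", "gene", "rho", "p_raw", "fdr_global", "fdr_local", "significant"],
    )
    return RegulatoryNetwork(cohort_id=cohort, edges=edges, graph=nx.DiGraph())


class TestUniversalInteractions:
    def _setup(self, n_he_cohorts, n_sig_cohorts, total=12):
        cohorts = [f"C{k}" for k in range(total)]
        he_map = {c: {"i—0"} if k < n_he_cohorts else set() for k, c in enumerate(cohorts)}
        nets = {
            c: _fake_network(c, [("i—0", "G")] if k < n_sig_cohorts else [])
            for k, c in enumerate(cohorts)
        }
        return nets, he_map

    def test_edge_kept_at_exactly_half(self):
        nets, he = self._setup(10, 5)
        graph = universal_interactions(nets, he)
        assert graph.has_edge("i—0", "G")
        assert graph.edges["i—0", "G"]["support"] == 5

    def test_edge_dropped_below_half(self):
        nets, he = self._setup(10, 4)
        assert universal_interactions(nets, he).number_of_edges() == 0

    def test_isomir_below_abundance_gate_excluded(self):
        nets, he = self._setup(9, 9)
        graph = universal_interactions(nets, he)
        assert "i—0" not in graph

    def test_invariant_under_cohort_order(self):
        nets, he = self._setup(10, 6)
        shuffled = dict(reversed(list(nets.items())))
        a = universal_interactions(nets, he)
        b = universal_interactions(shuffled, he)
        assert set(a.edges) == set(b.edges)

    def test_empty_cohort_map_rejected(self):
        with pytest.raises(NetworkError):
            universal_interactions({}, {})


class TestOraEnrichment:
    def test_disjoint_set_p_one(self):
        table = ora_enrichment({"a"}, {"S": ["x", "y"]}, {"a", "x", "y"})
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_closed_form_extreme_overlap(self):
        background = {f"g{j}" for j in range(20)}
        geneset = {f"g{j}" for j in range(5)}
        table = ora_enrichment(geneset, {"S": geneset}, background)
        assert table.loc[0, "p"] == pytest.approx(1.0 / math.comb(20, 5))

    def test_fdr_column_matches_bh(self, rng):
        background = {f"g{j}" for j in range(30)}
        query = set(rng.choice(sorted(background), size=8, replace=False))
        sets = {
            f"S{k}": rng.choice(sorted(background), size=10, replace=False).tolist()
            for k in range(3)
        }
        table = ora_enrichment(query, sets, background)
        assert np.allclose(table["fdr"], bh_oracle(table["p"].to_numpy()))

    def test_query_outside_background_rejected(self):
        with pytest.raises(NetworkError):
            ora_enrichment({"zz"}, {"S": ["a"]}, {"a", "b"})


class TestThresholds:
    def test_defaults_valid(self):
        PipelineThresholds()

    @pytest.mark.parametrize(
        "kwargs", [{"fdr_max": 1.5}, {"rho_max": -2.0}, {"mirdb_min": 150},
                   {"len_min": 0}, {"universal_min_fraction": 0.0}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(NetworkError):
            PipelineThresholds(**kwargs)
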