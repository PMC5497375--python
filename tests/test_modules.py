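"""Enrichment, functional-module selection, hub and pivot detection."""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import pivotnet as pn
from pivotnet.modules import (go_enrichment, select_functional_modules,
                              find_intermodular_hubs, identify_pivots,
                              pivot_module_report, ModuleSet)


def annotations_from(mapping):
    rows = [(g, t) for t, genes in mapping.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene", "term"])


def exact_upper_tail(k, N, K, n) -> float:
    """Arbitrary-precision hypergeometric P(X >= k)."""
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(n, K) + 1))
    return float(Fraction(num, comb(N, n)))


class TestGoEnrichment:
    def test_perfectly_specific_term_hits_combinatorial_minimum(self):
        universe = {f"u{i}" for i in range(100)}
        gene_set = set(list(universe)[:5])
        records = go_enrichment(gene_set, annotations_from({"T": gene_set}),
                                universe)
        assert records[0].p == pytest.approx(1 / comb(100, 5), rel=1e-12)

    def test_term_annotating_whole_universe_has_p_one(self):
        universe = {f"u{i}" for i in range(30)}
        records = go_enrichment(set(list(universe)[:6]),
                                annotations_from({"ALL": universe}), universe)
        assert records[0].p == pytest.approx(1.0)

    def test_terms_absent_from_gene_set_not_reported(self):
        universe = {"a", "b", "c", "d"}
        records = go_enrichment({"a"}, annotations_from({"T": {"b", "c"}}),
                                universe)
        assert records == []

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            go_enrichment(set(), annotations_from({}), set())

    def test_counts_satisfy_bounds(self, small_dataset):
        _, truth, _, go = small_dataset
        universe = set(truth.genes)
        records = go_enrichment(set(truth.module_members(0)), go, universe)
        for r in records:
            assert 0 < r.k <= min(r.K, r.n)
            assert r.q >= r.p


class TestFunctionalModules:
    def test_size_rule_excludes_nine_gene_cluster(self):
        genes = [f"g{i}" for i in range(9)]
        universe = set(genes) | {f"bg{i}" for i in range(50)}
        ms = select_functional_modules([set(genes)],
                                       annotations_from({"T": set(genes)}),
                                       universe)
        assert ms.functional == [False]

    def test_ten_gene_perfectly_annotated_cluster_is_functional(self):
        genes = {f"g{i}" for i in range(10)}
        universe = genes | {f"bg{i}" for i in range(50)}
        ms = select_functional_modules([genes], annotations_from({"T": genes}),
                                       universe)
        assert ms.functional == [True]

    def test_flag_matches_independent_two_condition_oracle(self, rng):
        universe = {f"g{i:03d}" for i in range(120)}
        pool = sorted(universe)
        clusters = []
        start = 0
        for size in (8, 12, 15, 20):
            clusters.append(set(pool[start:start + size]))
            start += size
        terms = {}
        for i, c in enumerate(clusters):
            members = list(c)
            n_hit = int(rng.integers(0, len(members) + 1))
            noise = list(rng.choice(pool, 10, replace=False))
            terms[f"T{i}"] = set(members[:n_hit]) | set(noise)
        ann = annotations_from(terms)
        ms = select_functional_modules(clusters, ann, universe,
                                       min_size=10, q_cutoff=0.05)
        for c, recs, flag in zip(ms.clusters, ms.enrichment, ms.functional):
            oracle = len(c) >= 10 and any(r.q <= 0.05 for r in recs)
            assert flag == oracle

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            ModuleSet([{"a"}, {"a", "b"}], [[], []], [False, False])


def star_network(hub, leaves, extra_edges=()):
    g = nx.Graph()
    for leaf in leaves:
        g.add_edge(hub, leaf)
    for u, v in extra_edges:
        g.add_edge(u, v)
    return g


class TestHubsAndPivots:
    def _modules(self, network, member_sets):
        universe = set(network.nodes)
        ann = annotations_from({f"T{i}": s for i, s in enumerate(member_sets)})
        # pad clusters so each is >= 10 genes and perfectly annotated
        return select_functional_modules(member_sets, ann, universe)

    def test_degree_ten_outside_modules_is_a_hub(self):
        members = {f"m{i}" for i in range(10)}
        g = star_network("h", members)
        for u in list(members)[1:]:
            g.add_edge(list(members)[0], u)  # make module internally connected
        g.add_nodes_from(f"bg{i}" for i in range(60))
        ms = self._modules(g, [members])
        assert ms.functional == [True]
        hubs = find_intermodular_hubs(g, ms, min_degree=10)
        assert hubs == ["h"]

    def test_high_degree_module_member_is_not_a_hub(self):
        members = {f"m{i}" for i in range(12)}
        g = nx.complete_graph(sorted(members))
        g.add_nodes_from(f"bg{i}" for i in range(60))
        ms = self._modules(g, [members])
        assert ms.functional == [True]
        assert find_intermodular_hubs(g, ms, min_degree=10) == []

    def test_degree_nine_is_not_a_hub(self):
        members = {f"m{i}" for i in range(9)}
        g = star_network("h", members)
        ms = ModuleSet([set(members)], [[]], [False])
        assert find_intermodular_hubs(g, ms, min_degree=10) == []

    def test_fully_concentrated_hub_hits_combinatorial_minimum(self):
        # hub with all 10 neighbours inside a 10-gene module, 200-node network
        members = [f"m{i}" for i in range(10)]
        g = star_network("h", members)
        for i in range(len(members)):
            g.add_edge(members[i], members[(i + 1) % len(members)])
        g.add_nodes_from(f"bg{i}" for i in range(189))
        assert g.number_of_nodes() == 200
        ms = self._modules(g, [set(members)])
        pivots = identify_pivots(["h"], g, ms)
        assert len(pivots) == 1
        p = pivots[0].module_stats[0][2]
        assert p == pytest.approx(exact_upper_tail(10, 199, 10, 10), rel=1e-12)
        assert p == pytest.approx(1 / comb(199, 10), rel=1e-12)

    def test_hub_with_no_module_neighbours_is_not_a_pivot(self):
        members = {f"m{i}" for i in range(10)}
        outside = {f"o{i}" for i in range(10)}
        g = star_network("h", outside)
        g.add_edges_from(nx.complete_graph(sorted(members)).edges)
        ms = self._modules(g, [members])
        assert identify_pivots(["h"], g, ms) == []

    def test_raising_min_degree_never_adds_hubs(self, small_dataset):
        expr, truth, ppi, go = small_dataset
        tpm = pn.compute_tpm(expr)
        net = pn.edge_correlation(pn.load_ppi(ppi), pn.log2_transform(tpm))
        clusters = pn.mcl_cluster(net)
        ms = select_functional_modules(clusters, go, set(net.nodes))
        h10 = set(find_intermodular_hubs(net, ms, min_degree=10))
        h12 = set(find_intermodular_hubs(net, ms, min_degree=12))
        assert h12 <= h10

    def test_lowering_p_cutoff_never_adds_pivots(self):
        members = [f"m{i}" for i in range(10)]
        g = star_network("h", members[:6], extra_edges=[("h", f"o{i}")
                                                        for i in range(6)])
        for i in range(len(members)):
            g.add_edge(members[i], members[(i + 1) % len(members)])
        g.add_nodes_from(f"bg{i}" for i in range(40))
        ms = self._modules(g, [set(members)])
        loose = {p.gene for p in identify_pivots(["h"], g, ms, p_cutoff=0.2)}
        tight = {p.gene for p in identify_pivots(["h"], g, ms, p_cutoff=0.01)}
        assert tight <= loose


class TestPlantedPivotRecovery:
    """Hub/pivot statistics recover the planted crosstalk genes.

    Functional modules are taken from the planted truth (intersected with
    the network's nodes); detection must find every planted pivot and flag
    no background gene in at least 18 of 20 simulation seeds.
    """

    def test_planted_pivots_recovered_in_most_seeds(self):
        perfect = 0
        for seed in range(20):
            expr, truth = pn.generate_stage_expression(
                n_genes=400, modules=[(20, 0.9), (20, 0.9)], n_pivots=3,
                de_spec={}, seed=seed)
            ppi = pn.generate_ppi(truth, p_background=0.01, seed=seed + 1000)
            tpm = pn.compute_tpm(expr)
            net = pn.edge_correlation(pn.load_ppi(ppi), pn.log2_transform(tpm))
            nodes = set(net.nodes)
            member_sets = [set(truth.module_members(m)) & nodes
                           for m in range(truth.n_modules)]
            go = pn.generate_go_annotations(truth, seed=seed)
            ms = select_functional_modules(member_sets, go, nodes)
            hubs = find_intermodular_hubs(net, ms, min_degree=10)
            pivots = {p.gene for p in identify_pivots(hubs, net, ms)}
            planted = {g for g, _, _ in truth.pivot_genes}
            background = set(truth.background_genes)
            if planted <= pivots and not (pivots & background):
                perfect += 1
        assert perfect >= 18


class TestPivotReport:
    def test_report_lists_one_block_per_enriched_module(self):
        m1 = {f"a{i}" for i in range(10)}
        m2 = {f"b{i}" for i in range(10)}
        g = nx.Graph()
        for members in (sorted(m1), sorted(m2)):
            for i in range(10):
                g.add_edge(members[i], members[(i + 1) % 10])
        for u in sorted(m1)[:6] + sorted(m2)[:6]:
            g.add_edge("h", u, sign="correlated")
        g.add_nodes_from(f"bg{i}" for i in range(80))
        ann = annotations_from({"T1": m1, "T2": m2})
        ms = select_functional_modules([m1, m2], ann, set(g.nodes))
        assert ms.functional == [True, True]
        pivots = identify_pivots(["h"], g, ms)
        assert pivots and set(pivots[0].enriched_modules) == {0, 1}
        report = pivot_module_report(pivots, ms, g)
        assert len(report) == 2
        assert set(report["pivot"]) == {"h"}

    def test_sign_breakdown_counts_anticorrelated_edges(self):
        members = {f"m{i}" for i in range(10)}
        g = nx.Graph()
        nodes = sorted(members)
        for i in range(10):
            g.add_edge(nodes[i], nodes[(i + 1) % 10])
        for u in nodes[:6]:
            g.add_edge("h", u, sign="anti-correlated")
        g.add_nodes_from(f"bg{i}" for i in range(50))
        ann = annotations_from({"T": members})
        ms = select_functional_modules([members], ann, set(g.nodes))
        pivots = identify_pivots(["h"], g, ms)
        report = pivot_module_report(pivots, ms, g)
        assert report.loc[0, "edges_anticorrelated"] == 6
        assert report.loc[0, "edges_correlated"] == 0
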