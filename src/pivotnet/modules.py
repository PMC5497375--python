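"""Functional modules, inter-modular hubs and pivot genes.

A *functional module* is an MCL cluster of at least ten genes significantly
enriched (one-sided hypergeometric, BH-adjusted q <= 0.05) for at least one
GO biological-process term.  An *inter-modular hub* is a gene outside all
functional modules with at least ten interactions in the co-expression
network.  A *pivot gene* is a hub whose neighbours are concentrated in some
functional module far beyond chance (one-sided hypergeometric p <= 0.05),
interpreted as mediating crosstalk between modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import networkx as nx
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentRecord",
    "ModuleSet",
    "PivotRecord",
    "go_enrichment",
    "select_functional_modules",
    "find_intermodular_hubs",
    "identify_pivots",
    "pivot_module_report",
]


@dataclass
class EnrichmentRecord:
    """One term's hypergeometric enrichment in one gene set.

    ``k`` annotated genes in the set, out of ``K`` annotated in the universe,
    with set size ``n`` and universe size ``N``; ``p = P(X >= k)`` for
    ``X ~ Hypergeometric(N, K, n)``; ``q`` is BH-adjusted across the terms
    tested for the same gene set.
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


@dataclass
class ModuleSet:
    """Disjoint clusters with per-cluster enrichment and functional flags."""

    clusters: list[set]
    enrichment: list[list[EnrichmentRecord]]
    functional: list[bool]

    def __post_init__(self) -> None:
        seen: set = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters must be pairwise disjoint")
            seen |= c

    @property
    def functional_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.functional) if f]

    def functional_members(self) -> set:
        out: set = set()
        for i in self.functional_indices:
            out |= self.clusters[i]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cluster in enumerate(self.clusters):
            for g in sorted(cluster):
                rows.append((g, i, self.functional[i]))
        return pd.DataFrame(rows, columns=["gene", "cluster", "functional"])

    def enrichment_frame(self) -> pd.DataFrame:
        rows = []
        for i, records in enumerate(self.enrichment):
            for r in records:
                rows.append((i, r.term, r.k, r.K, r.n, r.N, r.p, r.q))
        return pd.DataFrame(rows, columns=["cluster", "term", "k", "K", "n", "N",
                                           "p", "q"])


@dataclass
class PivotRecord:
    """An inter-modular hub with its per-module enrichment statistics."""

    gene: str
    degree: int
    module_stats: list[tuple[int, int, float]]  # (module index, k_module, p)
    enriched_modules: list[int] = field(default_factory=list)

    @property
    def is_pivot(self) -> bool:
        return bool(self.enriched_modules)


def _term_index(annotations) -> dict[str, set]:
    """term -> annotated gene set from a (gene, term) table or mapping."""
    if isinstance(annotations, pd.DataFrame):
        by_term: dict[str, set] = {}
        for gene, term in zip(annotations["gene"], annotations["term"]):
            by_term.setdefault(term, set()).add(gene)
        return by_term
    return {t: set(gs) for t, gs in annotations.items()}


def go_enrichment(gene_set, annotations, universe) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of annotation terms in a gene set.

    Only terms with at least one annotated gene in ``gene_set`` are tested
    (one-sided upper tail); BH adjustment runs across those terms.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    N, n = len(universe), len(gene_set)
    from .network import bh_adjust  # local import to avoid cycle

    records = []
    for term, annotated in sorted(_term_index(annotations).items()):
        ann_universe = annotated & universe
        k = len(annotated & gene_set)
        if k == 0:
            continue
        K = len(ann_universe)
        p = float(hypergeom.sf(k - 1, N, K, n))
        records.append(EnrichmentRecord(term, k, K, n, N, p, q=p))
    if records:
        qs = bh_adjust([r.p for r in records])
        for r, q in zip(records, qs):
            r.q = float(q)
    return records


def select_functional_modules(
    clusters,
    annotations,
    universe,
    min_size: int = 10,
    q_cutoff: float = 0.05,
) -> ModuleSet:
    """Flag clusters that qualify as co-expression functional gene modules.

    A cluster is functional iff it has at least ``min_size`` genes AND at
    least one term with BH-adjusted q <= ``q_cutoff``.
    """
    clusters = [set(c) for c in clusters]
    enrichment = [go_enrichment(c, annotations, universe) for c in clusters]
    functional = [
        len(c) >= min_size and any(r.q <= q_cutoff for r in recs)
        for c, recs in zip(clusters, enrichment)
    ]
    return ModuleSet(clusters, enrichment, functional)


def find_intermodular_hubs(
    network: nx.Graph,
    modules: ModuleSet,
    min_degree: int = 10,
) -> list[str]:
    """Genes outside every functional module with high network degree."""
    inside = modules.functional_members()
    return sorted(
        g for g in network.nodes
        if g not in inside and network.degree(g) >= min_degree
    )


def identify_pivots(
    hubs,
    network: nx.Graph,
    modules: ModuleSet,
    p_cutoff: float = 0.05,
) -> list[PivotRecord]:
    """Test each hub's neighbour concentration against each functional module.

    For hub h and functional module M: ``p = P(X >= k)`` with
    ``X ~ Hypergeometric(N - 1, |M|, deg(h))`` where N counts network nodes
    (the hub itself excluded from the sampling population) and k is the
    number of h's neighbours inside M.  A hub is a pivot iff some module has
    p <= ``p_cutoff``.
    """
    N = network.number_of_nodes()
    records = []
    for h in hubs:
        neighbours = set(network.neighbors(h))
        degree = len(neighbours)
        stats = []
        enriched = []
        for m in modules.functional_indices:
            members = modules.clusters[m]
            k = len(neighbours & members)
            p = float(hypergeom.sf(k - 1, N - 1, len(members), degree)) if k else 1.0
            stats.append((m, k, p))
            if k and p <= p_cutoff:
                enriched.append(m)
        records.append(PivotRecord(h, degree, stats, enriched))
    return [r for r in records if r.is_pivot]


def pivot_module_report(
    pivots: list[PivotRecord],
    modules: ModuleSet,
    network: nx.Graph | None = None,
    top_terms: int = 3,
) -> pd.DataFrame:
    """Tabular crosstalk report: one row per (pivot, enriched module).

    Lists the module's top GO terms (by q) and, when the co-expression
    network is given, the correlated / anti-correlated breakdown of the
    pivot's edges into the module.
    """
    rows = []
    for pivot in pivots:
        stat = {m: (k, p) for m, k, p in pivot.module_stats}
        for m in pivot.enriched_modules:
            k, p = stat[m]
            records = sorted(modules.enrichment[m], key=lambda r: (r.q, r.term))
            terms = ";".join(r.term for r in records[:top_terms])
            n_corr = n_anti = 0
            if network is not None:
                for nb in set(network.neighbors(pivot.gene)) & modules.clusters[m]:
                    if network.edges[pivot.gene, nb].get("sign") == "anti-correlated":
                        n_anti += 1
                    else:
                        n_corr += 1
            rows.append((pivot.gene, pivot.degree, m, len(modules.clusters[m]),
                         k, p, n_corr, n_anti, terms))
    return pd.DataFrame(rows, columns=[
        "pivot", "degree", "module", "module_size", "k_module", "p_hypergeom",
        "edges_correlated", "edges_anticorrelated", "top_terms",
    ])
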