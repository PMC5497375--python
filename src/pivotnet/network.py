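"""Co-expression network construction on a protein-interaction scaffold.

The scaffold is an undirected protein-protein interaction (PPI) graph; the
co-expression network keeps only the scaffold edges whose two genes show a
significant Pearson correlation across expression samples (Benjamini-
Hochberg adjusted p at or below a cutoff, 0.01 by default), annotated with
the correlation sign so correlated and anti-correlated interactions can be
distinguished downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = ["load_ppi", "bh_adjust", "edge_correlation", "write_network", "read_network"]

logger = logging.getLogger(__name__)

_TYPES = {"physical", "genetic", "unknown"}


def load_ppi(source, col_a: str = "gene_a", col_b: str = "gene_b",
             type_col: str = "interaction_type") -> nx.Graph:
    """Read an interaction edge table into a simple undirected graph.

    ``source`` is a tab-separated file path or a DataFrame with two id
    columns and an optional interaction-type column.  Self-interactions are
    dropped; duplicate edges in either orientation are merged keeping the
    first row's interaction type; drop counts are logged.  Rows with missing
    ids raise an error listing the offending line numbers.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source, sep="\t", dtype=str)
    for col in (col_a, col_b):
        if col not in table.columns:
            raise ValueError(f"missing id column {col!r}")
    bad = table.index[table[col_a].isna() | table[col_b].isna()
                      | (table[col_a].astype(str).str.strip() == "")
                      | (table[col_b].astype(str).str.strip() == "")]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"malformed rows at lines: {[int(i) + 2 for i in bad]}")

    graph = nx.Graph()
    n_self = n_dup = 0
    has_type = type_col in table.columns
    for row in table.itertuples(index=False):
        a, b = str(getattr(row, col_a)), str(getattr(row, col_b))
        kind = str(getattr(row, type_col)) if has_type else "unknown"
        if kind not in _TYPES:
            kind = "unknown"
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b, interaction_type=kind)
    logger.info("load_ppi: %d edges kept, %d self-interactions dropped, "
                "%d duplicates merged", graph.number_of_edges(), n_self, n_dup)
    return graph


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pearson_matrix_rows(X: np.ndarray) -> np.ndarray:
    """Row-standardize: zero mean, unit L2 norm; zero-variance rows -> NaN."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, Xc / norm, np.nan)


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the exact t transform.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom;
    ``|r| = 1`` maps to p = 0.
    """
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def edge_correlation(ppi: nx.Graph, expr, q_cutoff: float = 0.01) -> nx.Graph:
    """Overlay expression correlation on the PPI scaffold.

    For every scaffold edge whose two genes are present in ``expr`` with
    nonzero variance, the Pearson correlation across all samples and its
    two-sided p-value are computed; BH adjustment runs across all tested
    edges; edges with adjusted p (q) at or below ``q_cutoff`` are retained
    with ``r``, ``p``, ``q``, ``sign`` and the scaffold's interaction type.
    The returned graph's nodes are exactly the genes incident to a retained
    edge; counts of skipped edges live in ``graph.graph``.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    n = values.shape[1]
    if n < 3:
        raise ValueError("correlation p-values require at least 3 samples")
    genes = set(values.index)
    if not genes & set(ppi.nodes):
        raise ValueError("expression and PPI gene-id namespaces are disjoint")

    X = _pearson_matrix_rows(values.to_numpy(dtype=float))
    row = {g: i for i, g in enumerate(values.index)}

    tested: list[tuple[str, str, str]] = []
    rs: list[float] = []
    n_missing = n_constant = 0
    for a, b, data in ppi.edges(data=True):
        ia, ib = row.get(a), row.get(b)
        if ia is None or ib is None:
            n_missing += 1
            continue
        xa, xb = X[ia], X[ib]
        if np.isnan(xa[0]) or np.isnan(xb[0]):
            n_constant += 1
            continue
        tested.append((a, b, data.get("interaction_type", "unknown")))
        rs.append(float(np.clip(xa @ xb, -1.0, 1.0)))

    r_arr = np.array(rs)
    p_arr = correlation_pvalue(r_arr, n) if len(rs) else np.array([])
    q_arr = bh_adjust(p_arr) if len(rs) else np.array([])

    out = nx.Graph(n_tested=len(tested), n_skipped_missing=n_missing,
                   n_skipped_constant=n_constant, n_samples=n, q_cutoff=q_cutoff)
    for (a, b, kind), r, p, q in zip(tested, r_arr, p_arr, q_arr):
        if q <= q_cutoff:
            out.add_edge(a, b, r=float(r), p=float(p), q=float(q),
                         sign="anti-correlated" if r < 0 else "correlated",
                         interaction_type=kind)
    logger.info("edge_correlation: %d/%d edges retained (q <= %g); "
                "%d skipped for missing genes, %d for zero variance",
                out.number_of_edges(), len(tested), q_cutoff, n_missing, n_constant)
    return out


def write_network(network: nx.Graph, edge_path, gml_path=None) -> None:
    """Write the co-expression network as a TSV edge list (and optional GML)."""
    rows = [
        (a, b, d.get("r"), d.get("p"), d.get("q"), d.get("sign"),
         d.get("interaction_type"))
        for a, b, d in sorted(network.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "q", "sign",
                                "interaction_type"]).to_csv(edge_path, sep="\t",
                                                            index=False)
    if gml_path is not None:
        nx.write_gml(network, gml_path)


def read_network(edge_path) -> nx.Graph:
    table = pd.read_csv(edge_path, sep="\t")
    g = nx.Graph()
    for row in table.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, r=row.r, p=row.p, q=row.q,
                   sign=row.sign, interaction_type=row.interaction_type)
    return g
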