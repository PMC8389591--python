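"""Hub-gene nomination from a survival-associated module.

Module genes are ranked by weighted degree and by eigenvector centrality
of the weighted module subgraph; over-representation of the module in a
local gene-set collection picks the significant pathways; the top-k sets
from both centralities, the pathway member genes, and an external DEG
list are intersected to give the final hub set.  Pairwise Spearman
correlations among hubs characterise their co-expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CentralityRanking:
    kind: str  # weighted_degree | eigenvector
    scores: dict[str, float]
    top_k: tuple[str, ...]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    p_adj: float
    overlap_genes: tuple[str, ...]


def _eigenvector_power(G: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000) -> dict[str, float]:
    nodes = sorted(G.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, d in G.edges(data=True):
        w = float(d.get("weight", 1.0))
        A[idx[u], idx[v]] = w
        A[idx[v], idx[u]] = w
    # positive spectral shift keeps the principal eigenvalue strictly
    # dominant (bipartite adjacency alone oscillates under power iteration)
    shift = 1.0 + float(A.sum(axis=1).max())
    x = np.ones(len(nodes)) / np.sqrt(len(nodes))
    for _ in range(max_iter):
        y = A @ x + shift * x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    n = np.linalg.norm(x)
    if n > 0:
        x = x / n
    return {node: float(x[idx[node]]) for node in nodes}


def rank_centrality(module_graph: nx.Graph, kind: str, k: int = 10) -> CentralityRanking:
    """Rank module genes by weighted-degree or eigenvector centrality.

    Eigenvector centrality is the principal eigenvector of the weighted
    adjacency (power iteration, tolerance 1e-10, unit Euclidean norm);
    on a disconnected module it is computed on the largest connected
    component with a warning, other nodes scoring 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if module_graph.number_of_nodes() == 0:
        raise ValueError("empty module graph")
    if kind == "weighted_degree":
        scores = {
            n: float(sum(d.get("weight", 1.0) for d in module_graph[n].values()))
            for n in module_graph.nodes
        }
    elif kind == "eigenvector":
        if nx.is_connected(module_graph):
            scores = _eigenvector_power(module_graph)
        else:
            logger.warning("module graph disconnected; eigenvector on largest component")
            comp = max(nx.connected_components(module_graph), key=lambda c: (len(c), sorted(c)))
            sub_scores = _eigenvector_power(module_graph.subgraph(comp))
            scores = {n: sub_scores.get(n, 0.0) for n in module_graph.nodes}
    else:
        raise ValueError(f"unknown centrality kind: {kind!r}")
    ordered = sorted(scores, key=lambda g: (-scores[g], g))
    return CentralityRanking(kind=kind, scores=scores, top_k=tuple(ordered[:k]))


def hypergeometric_enrichment(
    query,
    gene_sets: dict[str, list[str]],
    universe,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each gene set.

    p = P(X >= overlap) for X ~ Hypergeom(N=|universe|, K=|set|,
    n=|query|); sets are first intersected with the universe; BH
    adjustment is applied across sets; results sorted by p then name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & uni
        overlap = sorted(q & members)
        p = float(stats.hypergeom.sf(len(overlap) - 1, len(uni), len(members), len(q)))
        results.append(
            {
                "set_name": name,
                "overlap": len(overlap),
                "set_size": len(members),
                "query_size": len(q),
                "universe_size": len(uni),
                "p": min(p, 1.0),
                "overlap_genes": tuple(overlap),
            }
        )
    p_adj = bh_adjust([r["p"] for r in results]) if results else []
    out = [
        EnrichmentResult(p_adj=float(adj), **r)
        for r, adj in zip(results, p_adj)
    ]
    out.sort(key=lambda r: (r.p, r.set_name))
    return out


def significant_pathway_genes(
    enrichment: list[EnrichmentResult],
    module_genes,
    alpha: float = 0.05,
    top_n: int = 10,
) -> set[str]:
    """Union of member genes of the top-n sets with p < alpha, within the module."""
    sig = [r for r in enrichment if r.p < alpha][:top_n]
    genes: set[str] = set()
    for r in sig:
        genes.update(r.overlap_genes)
    return genes & set(module_genes)


def intersect_hubs(set_a, set_b, set_c, set_d) -> set[str]:
    """Exact four-way intersection (degree top-k, eigenvector top-k,
    pathway genes, external DEGs)."""
    return set(set_a) & set(set_b) & set(set_c) & set(set_d)


def hub_correlations(expr: pd.DataFrame, hubs, method: str = "spearman") -> pd.DataFrame:
    """Pairwise hub-gene correlation matrix across the given samples.

    Spearman by default (Pearson via ``method``); a constant gene yields
    NaN against every partner; diagonal is 1 for non-constant genes.
    """
    hubs = sorted(hubs)
    missing = [g for g in hubs if g not in expr.index]
    if missing:
        raise KeyError(f"hub gene(s) missing from expression: {missing}")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlations")
    X = expr.loc[hubs].to_numpy(dtype=float)
    if method == "spearman":
        ranked = np.apply_along_axis(stats.rankdata, 1, X)
    elif method == "pearson":
        ranked = X
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    sd = ranked.std(axis=1)
    with np.errstate(invalid="ignore"):  # constant rows -> NaN, reported as missing
        C = np.corrcoef(ranked)
    C = np.atleast_2d(C)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    np.fill_diagonal(C, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(C, index=hubs, columns=hubs)
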