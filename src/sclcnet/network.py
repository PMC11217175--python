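"""Weighted co-expression network construction and spanning-tree hub calling.

The network over a user-supplied gene panel (e.g. cancer-pathway genes) is
built from pairwise Pearson correlations raised to a soft-threshold power
(unsigned ``|r|**beta`` by default, signed ``((1+r)/2)**beta`` optionally).
Two filtering stages follow, in this order:

1. every edge with weight <= ``min_weight`` is removed (strict ``>`` kept);
2. each node marks the top ``ceil(top_frac * incident_count)`` of its
   surviving incident edges (weight descending, ties by lexicographic
   partner id); an edge survives iff marked by at least one endpoint.

Hubs are read from the minimum spanning forest of the filtered network under
edge distance ``1 - weight`` (the maximum-total-weight spanning forest):
a gene is a hub when its forest degree is strictly greater than
``hub_degree_gt``.  All tie-breaking is by lexicographic node-pair order so
identical inputs always yield identical forests and hub calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .scoring import EnrichmentMatrix

__all__ = [
    "NetworkConfig",
    "build_adjacency",
    "filter_network",
    "spanning_forest",
    "find_hubs",
    "hub_cell_correlation",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Thresholds of the network stage.

    beta : soft-threshold power applied to the correlation.
    signed : use ((1+r)/2)**beta instead of |r|**beta.
    min_weight : edge retention floor (strictly greater survives).
    top_frac : per-gene retained fraction of incident edges.
    hub_degree_gt : forest degree strictly above which a gene is a hub.
    """

    beta: int = 6
    signed: bool = False
    min_weight: float = 0.01
    top_frac: float = 0.30
    hub_degree_gt: int = 4

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be a positive integer")
        if not (0 < self.top_frac <= 1):
            raise ValueError("top_frac must be in (0, 1]")
        if not (0 <= self.min_weight < 1):
            raise ValueError("min_weight must be in [0, 1)")
        if self.hub_degree_gt < 0:
            raise ValueError("hub_degree_gt must be >= 0")


def build_adjacency(
    X: ExpressionMatrix, panel: list[str], config: NetworkConfig = NetworkConfig()
) -> nx.Graph:
    """Complete weighted graph over ``panel`` from soft-thresholded correlations."""
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sub = X.subset_genes(panel)
    vals = sub.values()
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = np.asarray(panel)[sd == 0][0]
        raise ValueError(f"panel gene {bad!r} has zero variance across samples")
    corr = np.corrcoef(vals)
    if config.signed:
        adj = ((1.0 + corr) / 2.0) ** config.beta
    else:
        adj = np.abs(corr) ** config.beta
    adj = np.clip(adj, 0.0, 1.0)
    G = nx.Graph()
    G.add_nodes_from(panel)
    order = np.argsort(np.asarray(panel, dtype=object))
    # add edges in lexicographic pair order for reproducible iteration
    for ii in range(len(panel)):
        u_idx = order[ii]
        for jj in range(ii + 1, len(panel)):
            v_idx = order[jj]
            G.add_edge(panel[u_idx], panel[v_idx], weight=float(adj[u_idx, v_idx]))
    return G


def filter_network(G: nx.Graph, config: NetworkConfig = NetworkConfig()) -> nx.Graph:
    """Two-stage edge filter: weight floor, then per-node top fraction.

    Stage 1 keeps edges with weight strictly greater than ``min_weight``.
    Stage 2, on the surviving graph, has each node mark its strongest
    ``ceil(top_frac * incident_count)`` edges (ties by lexicographic partner
    id); an edge is kept iff at least one endpoint marked it.  Nodes are
    never dropped, so isolated genes remain in the node set.
    """
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    surviving = [
        (u, v, d["weight"])
        for u, v, d in G.edges(data=True)
        if d["weight"] > config.min_weight
    ]
    inc: dict[str, list[tuple[float, str, str]]] = {n: [] for n in G.nodes}
    for u, v, w in surviving:
        inc[u].append((w, v, u))
        inc[v].append((w, u, v))
    marked: set[frozenset] = set()
    for node, edges in inc.items():
        if not edges:
            continue
        edges.sort(key=lambda t: (-t[0], t[1]))
        k = math.ceil(config.top_frac * len(edges))
        for w, partner, _ in edges[:k]:
            marked.add(frozenset((node, partner)))
    for u, v, w in surviving:
        if frozenset((u, v)) in marked:
            H.add_edge(u, v, weight=w)
    return H


def spanning_forest(G: nx.Graph) -> nx.Graph:
    """Minimum spanning forest under distance 1 - weight (Kruskal).

    Equivalently the maximum-total-weight spanning forest: the strongest
    co-expression edges are kept.  Ties are broken by (distance,
    lexicographic node pair), so the forest is unique given the input.
    Returns one tree per connected component; an empty graph yields an
    empty forest.
    """
    forest = nx.Graph()
    forest.add_nodes_from(G.nodes)
    edges = []
    for u, v, d in G.edges(data=True):
        a, b = sorted((u, v))
        edges.append((1.0 - d["weight"], a, b, d["weight"]))
    edges.sort(key=lambda t: (t[0], t[1], t[2]))
    uf = nx.utils.UnionFind(G.nodes)
    for dist, a, b, w in edges:
        if uf[a] != uf[b]:
            uf.union(a, b)
            forest.add_edge(a, b, weight=w, distance=dist)
    return forest


def find_hubs(
    F: nx.Graph, config: NetworkConfig = NetworkConfig()
) -> pd.DataFrame:
    """Hub report: every gene with its forest degree and hub call.

    A gene is a hub iff its degree in the spanning forest is strictly
    greater than ``hub_degree_gt``.  Sorted by degree descending then id.
    """
    records = [
        {"gene_id": n, "degree": int(F.degree[n]), "is_hub": F.degree[n] > config.hub_degree_gt}
        for n in F.nodes
    ]
    out = pd.DataFrame.from_records(
        records, columns=["gene_id", "degree", "is_hub"]
    )
    return out.sort_values(
        ["degree", "gene_id"], ascending=[False, True], ignore_index=True
    )


def hub_cell_correlation(
    X: ExpressionMatrix, hubs: list[str], E: EnrichmentMatrix
) -> pd.DataFrame:
    """Pearson correlation of each hub gene's expression with each signature score.

    Computed over the samples shared between the expression matrix and the
    enrichment matrix; the two-sided p-value comes from the usual t
    transform on n - 2 degrees of freedom (p = 0 at r = +/-1).  A constant
    vector yields a flagged record with undefined r.
    """
    shared = [s for s in X.sample_ids if s in set(E.sample_ids)]
    if len(shared) < 3:
        raise ValueError(
            f"need >=3 shared samples for correlation (got {len(shared)})"
        )
    Xs = X.subset_genes(hubs).subset_samples(shared)
    records = []
    for gene in hubs:
        gv = Xs.data.loc[gene].to_numpy(dtype=float)
        for set_name in E.set_names:
            ev = E.data.loc[set_name, shared].to_numpy(dtype=float)
            if gv.std() == 0 or ev.std() == 0:
                records.append(
                    {"gene_id": gene, "set_name": set_name, "r": np.nan,
                     "p_value": np.nan, "n": len(shared), "degenerate": True}
                )
                continue
            r, p = stats.pearsonr(gv, ev)
            if abs(r) >= 1.0 - 1e-15:
                r, p = math.copysign(1.0, r), 0.0
            records.append(
                {"gene_id": gene, "set_name": set_name, "r": float(r),
                 "p_value": float(p), "n": len(shared), "degenerate": False}
            )
    return pd.DataFrame.from_records(records)


def write_edge_list(G: nx.Graph, path) -> None:
    """Edge list TSV (node_a, node_b, weight), lexicographic pair order."""
    rows = sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in G.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.10g}\n")
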