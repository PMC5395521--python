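"""Similarity networks, the drug-target affinity network, and node scores.

Two graph kinds feed the feature engineering:

* thresholded similarity graphs over drugs and over targets -- an edge exists
  iff similarity is strictly above a user threshold (edge weight = similarity);
* the bipartite affinity graph whose nodes are drugs and targets and whose
  edges are the *training* observations (edge weight = affinity).

Node scores are betweenness, closeness, eigenvector centrality and PageRank.
Betweenness and closeness use unweighted (hop-count) shortest paths on both
graph kinds; eigenvector centrality and PageRank use edge weights as adjacency
weights.  On disconnected graphs eigenvector centrality is computed on the
largest connected component and is zero elsewhere (the principal eigenvector
is not unique across components).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .data_io import AffinityMatrix, SimilarityMatrix
from .errors import ConfigError, NumericalError

__all__ = [
    "build_similarity_graph",
    "build_bipartite_graph",
    "node_centralities",
    "knn_summary",
    "pair_network_averages",
]

PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-9
EIGENVECTOR_TOL = 1e-8
EIGENVECTOR_MAX_ITER = 5000


def build_similarity_graph(s: SimilarityMatrix, threshold: float) -> nx.Graph:
    """Graph over entities with an edge iff similarity > threshold (strict).

    Isolated nodes are retained; no self-loops.
    """
    if not (0.0 <= threshold < 1.0):
        raise ConfigError("similarity threshold must lie in [0, 1)")
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(s.ids)
    n = s.n
    iu, ju = np.triu_indices(n, k=1)
    above = s.values[iu, ju] > threshold
    g.add_weighted_edges_from(
        (s.ids[i], s.ids[j], float(s.values[i, j]))
        for i, j in zip(iu[above], ju[above])
    )
    return g


def build_bipartite_graph(m: AffinityMatrix) -> nx.Graph:
    """Bipartite graph of training observations; edge weight = affinity.

    Nodes are ``("drug", id)`` / ``("target", id)`` tuples so drug and target
    id namespaces can never collide; no within-part edges can exist by
    construction.
    """
    g = nx.Graph()
    g.add_nodes_from((("drug", d) for d in m.drug_ids), bipartite=0)
    g.add_nodes_from((("target", t) for t in m.target_ids), bipartite=1)
    rows, cols = np.nonzero(m.observed)
    g.add_weighted_edges_from(
        (("drug", m.drug_ids[i]), ("target", m.target_ids[j]), float(m.values[i, j]))
        for i, j in zip(rows, cols)
    )
    return g


def _largest_component(g: nx.Graph) -> set:
    # most nodes; ties broken by the component containing the smallest node id
    comps = list(nx.connected_components(g))
    max_size = max(len(c) for c in comps)
    return min((c for c in comps if len(c) == max_size),
               key=lambda c: min(map(str, c)))


def node_centralities(g: nx.Graph) -> dict:
    """Per-node scores: ``{node: {"bt": ..., "cl": ..., "ev": ..., "pr": ...}}``.

    PageRank scores sum to 1; eigenvector centrality has unit Euclidean norm
    on the component where it is defined.
    """
    if g.number_of_nodes() == 0:
        raise ConfigError("centralities require a non-empty graph")
    bt = nx.betweenness_centrality(g, normalized=True)
    cl = nx.closeness_centrality(g)
    pr = nx.pagerank(g, alpha=PAGERANK_DAMPING, tol=PAGERANK_TOL,
                     max_iter=1000, weight="weight")
    ev = {node: 0.0 for node in g.nodes}
    comp = _largest_component(g)
    sub = g.subgraph(comp)
    if sub.number_of_edges() > 0:
        nodes = sorted(sub.nodes, key=str)
        adj = nx.to_numpy_array(sub, nodelist=nodes, weight="weight")
        vec = _principal_eigenvector(adj, comp)
        for node, v in zip(nodes, vec):
            ev[node] = float(v)
    return {node: {"bt": bt[node], "cl": cl[node], "ev": ev[node], "pr": pr[node]}
            for node in g.nodes}


def _principal_eigenvector(adj: np.ndarray, comp) -> np.ndarray:
    """Unit-norm Perron eigenvector of a connected nonnegative adjacency.

    Power iteration on the shifted matrix A + cI (same eigenvectors, strictly
    dominant principal eigenvalue even on bipartite graphs, whose spectra are
    symmetric about 0).  The shift c is the maximum weighted degree, which
    bounds the spectral radius.
    """
    n = adj.shape[0]
    shift = float(adj.sum(axis=1).max())
    x = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(EIGENVECTOR_MAX_ITER):
        y = adj @ x + shift * x
        y /= np.linalg.norm(y)
        if np.abs(y - x).max() < EIGENVECTOR_TOL:
            return np.abs(y)
        x = y
    raise NumericalError(
        f"eigenvector centrality failed to converge within "
        f"{EIGENVECTOR_MAX_ITER} iterations on the component containing "
        f"{sorted(map(str, comp))[:5]}")


def knn_summary(s: SimilarityMatrix, graph: nx.Graph, node: str, k: int,
                type1_table: dict[str, np.ndarray]) -> dict:
    """k-nearest-neighbour summaries for one node of a thresholded graph.

    Neighbours are the node's graph neighbours ranked by similarity
    (descending; ties broken by ascending id).  Returns::

        num_nb       degree in the thresholded graph
        k_sim        top-k similarities, descending, zero-padded to length k
        k_ave_feat   unweighted elementwise mean of the (<= k) neighbours'
                     Type-1 vectors; NaN vector if no neighbours
        k_w_ave_feat similarity-weighted mean, weights normalised to sum 1
                     (uniform fallback if all similarities are 0)
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    idx = s.ids.index(node)
    nbrs = sorted(graph.neighbors(node),
                  key=lambda other: (-s.values[idx, s.ids.index(other)], other))
    top = nbrs[:k]
    sims = np.array([s.values[idx, s.ids.index(other)] for other in top])
    k_sim = np.zeros(k)
    k_sim[:len(top)] = sims

    feat_len = len(next(iter(type1_table.values())))
    if not top:
        k_ave = np.full(feat_len, np.nan)
        k_w_ave = np.full(feat_len, np.nan)
    else:
        feats = np.vstack([type1_table[other] for other in top])
        k_ave = np.nanmean(feats, axis=0)
        total = sims.sum()
        weights = sims / total if total > 0 else np.full(len(top), 1.0 / len(top))
        # weighted mean ignoring NaN entries per column, renormalising weights
        k_w_ave = np.empty(feat_len)
        for c in range(feat_len):
            col = feats[:, c]
            ok = np.isfinite(col)
            wsum = weights[ok].sum()
            k_w_ave[c] = (weights[ok] @ col[ok]) / wsum if wsum > 0 else np.nan
    return {"num_nb": graph.degree(node), "k_sim": k_sim,
            "k_ave_feat": k_ave, "k_w_ave_feat": k_w_ave}


def pair_network_averages(m_train: AffinityMatrix, g_drug: nx.Graph,
                          g_target: nx.Graph, drug_id: str,
                          target_id: str) -> tuple[float, float]:
    """Read-across averages over similarity-graph neighbours.

    ``d_t_ave``: mean of the drug's observed training affinities with the
    target's neighbours in the target similarity graph; ``t_d_ave`` is the
    symmetric quantity over the drug's neighbours.  NaN (the tree learner's
    native missing marker) when no qualifying observation exists.
    """
    i = m_train.drug_index(drug_id)
    j = m_train.target_index(target_id)

    t_nbrs = [m_train.target_index(t) for t in g_target.neighbors(target_id)]
    vals = [m_train.values[i, jj] for jj in t_nbrs if m_train.observed[i, jj]]
    d_t_ave = float(np.mean(vals)) if vals else float("nan")

    d_nbrs = [m_train.drug_index(d) for d in g_drug.neighbors(drug_id)]
    vals = [m_train.values[ii, j] for ii in d_nbrs if m_train.observed[ii, j]]
    t_d_ave = float(np.mean(vals)) if vals else float("nan")
    return d_t_ave, t_d_ave
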