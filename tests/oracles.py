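"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths of the package (and of networkx where
practical): betweenness/closeness come from explicit BFS path enumeration,
eigenvector centrality from a dense symmetric eigendecomposition, PageRank
from the dense Google-matrix eigenproblem, and the concordance index from a
double loop over pairs.
"""

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj_list, source, n):
    dist = [None] * n
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj_list[u]:
            if dist[v] is None:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _count_paths(adj_list, dist, s, t):
    """Number of shortest s-t paths and, per node, paths through that node."""
    n = len(adj_list)
    sigma = [0] * n
    sigma[s] = 1
    order = sorted((d, v) for v, d in enumerate(dist) if d is not None)
    for _, v in order:
        if v == s:
            continue
        sigma[v] = sum(sigma[u] for u in adj_list[v]
                       if dist[u] is not None and dist[u] == dist[v] - 1)
    return sigma


def betweenness_oracle(adj_matrix):
    """Normalized betweenness by explicit shortest-path counting."""
    n = adj_matrix.shape[0]
    adj_list = [np.nonzero(adj_matrix[i])[0].tolist() for i in range(n)]
    score = np.zeros(n)
    for s, t in combinations(range(n), 2):
        dist_s = bfs_distances(adj_list, s, n)
        if dist_s[t] is None:
            continue
        sigma_s = _count_paths(adj_list, dist_s, s, t)
        dist_t = bfs_distances(adj_list, t, n)
        sigma_t = _count_paths(adj_list, dist_t, t, s)
        total = sigma_s[t]
        for v in range(n):
            if v in (s, t) or dist_s[v] is None or dist_t[v] is None:
                continue
            if dist_s[v] + dist_t[v] == dist_s[t]:
                score[v] += sigma_s[v] * sigma_t[v] / total
    if n > 2:
        score /= (n - 1) * (n - 2) / 2.0
    return score


def closeness_oracle(adj_matrix):
    """Closeness with the component-fraction scaling for disconnected graphs."""
    n = adj_matrix.shape[0]
    adj_list = [np.nonzero(adj_matrix[i])[0].tolist() for i in range(n)]
    out = np.zeros(n)
    for u in range(n):
        dist = bfs_distances(adj_list, u, n)
        reach = [d for d in dist if d is not None]
        r = len(reach)
        total = sum(reach)
        if r > 1 and total > 0:
            out[u] = ((r - 1) / total) * ((r - 1) / (n - 1))
    return out


def eigenvector_oracle(weighted_adj):
    """Principal eigenvector of the largest component via dense eigh."""
    n = weighted_adj.shape[0]
    # connected components on the unweighted support
    support = weighted_adj > 0
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        comp = []
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(support[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    max_size = max(len(c) for c in comps)
    comp = min((c for c in comps if len(c) == max_size), key=lambda c: c[0])
    out = np.zeros(n)
    sub = weighted_adj[np.ix_(comp, comp)]
    if sub.sum() == 0:
        return out
    w, v = np.linalg.eigh(sub)
    vec = np.abs(v[:, np.argmax(w)])
    out[comp] = vec / np.linalg.norm(vec)
    return out


def pagerank_oracle(weighted_adj, damping=0.85):
    """Stationary vector of the dense Google matrix (eigendecomposition)."""
    n = weighted_adj.shape[0]
    deg = weighted_adj.sum(axis=1)
    s = np.zeros((n, n))
    for i in range(n):
        if deg[i] > 0:
            s[i] = weighted_adj[i] / deg[i]
        else:
            s[i] = 1.0 / n  # dangling node: uniform jump
    google = damping * s + (1 - damping) / n
    w, v = np.linalg.eig(google.T)
    vec = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    vec = np.abs(vec)
    return vec / vec.sum()


def concordance_oracle(y, yhat):
    """O(n^2) double loop over the definition."""
    num = 0.0
    den = 0
    n = len(y)
    for i in range(n):
        for j in range(i + 1, n):
            if y[i] == y[j]:
                continue
            den += 1
            if yhat[i] == yhat[j]:
                num += 0.5
            elif (yhat[i] - yhat[j]) * (y[i] - y[j]) > 0:
                num += 1.0
    return num / den
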