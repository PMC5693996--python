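"""Independent brute-force oracles used to validate the implementation.

Everything here deliberately avoids the code paths of the package:
shortest paths by exhaustive simple-path enumeration, components by
networkx, t statistics by scipy, enumeration p-values by itertools.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import stats as sps

_REL_TOL = 1e-12


def _simple_paths(w: np.ndarray, s: int, t: int):
    """All simple paths s -> t over positive-weight edges."""
    n = w.shape[0]
    adj = [np.flatnonzero(w[i] > 0) for i in range(n)]
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nbr in adj[node]:
            if nbr not in path:
                stack.append((int(nbr), path + [int(nbr)]))


def _path_length(w: np.ndarray, path: list[int]) -> float:
    return sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))


def brute_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest 1/w path lengths by enumeration."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            best = np.inf
            for path in _simple_paths(w, s, t):
                best = min(best, _path_length(w, path))
            d[s, t] = d[t, s] = best
    return d


def brute_strength(w: np.ndarray) -> np.ndarray:
    return np.array([w[i].sum() for i in range(w.shape[0])])


def brute_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering from the definition."""
    n = w.shape[0]
    wmax = w.max()
    what = w / wmax if wmax > 0 else w
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            total += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * total / (k * (k - 1))
    return out


def brute_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = brute_distances(w)
    out = np.zeros(n)
    for i in range(n):
        inv = [1.0 / d[i, j] for j in range(n)
               if j != i and np.isfinite(d[i, j])]
        out[i] = sum(inv) / (n - 1)
    return out


def brute_betweenness(w: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by enumerating all shortest paths."""
    n = w.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            lengths = []
            paths = []
            for path in _simple_paths(w, s, t):
                lengths.append(_path_length(w, path))
                paths.append(path)
            if not paths:
                continue
            best = min(lengths)
            shortest = [p for p, ln in zip(paths, lengths)
                        if ln <= best * (1 + _REL_TOL)]
            sigma = len(shortest)
            for node in range(n):
                if node in (s, t):
                    continue
                through = sum(1 for p in shortest if node in p)
                out[node] += through / sigma
    return out


def components_by_networkx(edges_with_t: dict, threshold: float):
    """Suprathreshold components via networkx, sorted like the package."""
    g = nx.Graph()
    for (a, b), t in edges_with_t.items():
        if t > threshold:
            g.add_edge(a, b)
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        comps.append((frozenset(tuple(sorted(e)) for e in sub.edges()),
                      frozenset(nodes)))
    comps.sort(key=lambda c: (-len(c[0]), min(c[1])))
    return comps


def exact_nbs_pvalue(x: np.ndarray, is_b: np.ndarray, pairs: list,
                     threshold: float) -> float:
    """Exhaustive-enumeration p for the largest observed component.

    ``x``: subjects x edges; ``pairs``: (label_i, label_j) per column.
    Enumerates every split of the pooled sample into groups of the
    observed sizes, forming max component size from t > threshold
    (contrast b - a), and returns the fraction at least as large as the
    observed maximal component.
    """
    s = x.shape[0]
    nb = int(is_b.sum())

    def max_size(mask_b: np.ndarray) -> int:
        t = sps.ttest_ind(x[mask_b], x[~mask_b], axis=0).statistic
        t = np.nan_to_num(t)
        ew = {pairs[e]: t[e] for e in range(len(pairs))}
        comps = components_by_networkx(ew, threshold)
        return len(comps[0][0]) if comps else 0

    observed = max_size(is_b)
    sizes = []
    for combo in itertools.combinations(range(s), nb):
        mask = np.zeros(s, dtype=bool)
        mask[list(combo)] = True
        sizes.append(max_size(mask))
    return sum(1 for v in sizes if v >= observed) / len(sizes)
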