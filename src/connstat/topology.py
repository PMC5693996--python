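"""Weighted nodal topology measures on functional networks.

Conventions follow the Brain Connectivity Toolbox: connection weights are
affinities (stronger = closer), so shortest-path computations use the
edge length 1/w; clustering is the Onnela geometric-mean form with
weights normalized by the network maximum; betweenness is unnormalized
with fractional credit over tied shortest paths.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .cohort import CohortDataset
from .network import FunctionalNetwork

METRIC_COLUMNS = ("strength", "clustering", "efficiency", "betweenness")


def _graph(net: FunctionalNetwork, length: bool = False) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.n_regions))
    w = net.weights
    iu, ju = np.nonzero(np.triu(w, k=1))
    for i, j in zip(iu, ju):
        attrs = {"weight": w[i, j]}
        if length:
            attrs["length"] = 1.0 / w[i, j]
        g.add_edge(int(i), int(j), **attrs)
    return g


def _distance_matrix(net: FunctionalNetwork) -> np.ndarray:
    """All-pairs weighted shortest-path distances with length 1/w."""
    w = net.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def node_strength(net: FunctionalNetwork,
                  region: str | None = None) -> float | np.ndarray:
    """Sum of weights of the links connected to a node."""
    s = net.weights.sum(axis=1)
    if region is None:
        return s
    return float(s[net.index_of(region)])


def clustering_coefficient(net: FunctionalNetwork,
                           region: str | None = None) -> float | np.ndarray:
    """Onnela weighted clustering: mean cube-root triangle intensity
    around a node, with weights scaled by the network maximum; zero for
    nodes of degree < 2."""
    c = nx.clustering(_graph(net), weight="weight")
    vals = np.array([c[i] for i in range(net.n_regions)], dtype=float)
    if region is None:
        return vals
    return float(vals[net.index_of(region)])


def nodal_efficiency(net: FunctionalNetwork, region: str | None = None,
                     variant: str = "nodal") -> float | np.ndarray:
    """Mean inverse shortest-path distance from a node to all others
    (``variant="nodal"``), or the mean inverse distance among the node's
    neighbours within its neighbourhood subgraph (``variant="local"``).
    Unreachable pairs contribute zero."""
    n = net.n_regions
    if variant == "nodal":
        d = _distance_matrix(net)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        np.fill_diagonal(inv, 0.0)
        vals = inv.sum(axis=1) / (n - 1)
    elif variant == "local":
        vals = np.zeros(n)
        for i in range(n):
            nbrs = np.flatnonzero(net.weights[i] > 0)
            k = nbrs.size
            if k < 2:
                continue
            sub = FunctionalNetwork(
                net.subject_id,
                net.weights[np.ix_(nbrs, nbrs)],
                tuple(net.region_labels[j] for j in nbrs),
            )
            d = _distance_matrix(sub)
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
            np.fill_diagonal(inv, 0.0)
            vals[i] = inv.sum() / (k * (k - 1))
    else:
        raise ValueError(f"unknown efficiency variant {variant!r}")
    if region is None:
        return vals
    return float(vals[net.index_of(region)])


def betweenness_centrality(net: FunctionalNetwork,
                           region: str | None = None) -> float | np.ndarray:
    """Unnormalized weighted betweenness (Brandes): for each pair of
    other nodes, the fraction of weighted shortest paths (length 1/w)
    passing through the node, summed over unordered pairs."""
    b = nx.betweenness_centrality(_graph(net, length=True), weight="length",
                                  normalized=False)
    vals = np.array([b[i] for i in range(net.n_regions)], dtype=float)
    if region is None:
        return vals
    return float(vals[net.index_of(region)])


def compute_all(cohort: CohortDataset,
                regions: set[str] | None = None,
                efficiency_variant: str = "nodal") -> pd.DataFrame:
    """Long-form table of the four nodal measures for every subject.

    ``regions`` restricts the output rows (e.g. to hub regions); the
    measures themselves are always computed on the full network.
    """
    if not cohort.networks:
        raise ValueError("cohort has no networks")
    labels = cohort.region_labels
    keep = (list(range(len(labels))) if regions is None
            else sorted(cohort.networks[0].index_of(r) for r in regions))
    rows = []
    for net in cohort.networks:
        s = node_strength(net)
        c = clustering_coefficient(net)
        e = nodal_efficiency(net, variant=efficiency_variant)
        b = betweenness_centrality(net)
        for i in keep:
            rows.append({
                "subject_id": net.subject_id,
                "region": labels[i],
                "strength": s[i],
                "clustering": c[i],
                "efficiency": e[i],
                "betweenness": b[i],
            })
    return pd.DataFrame(rows)


def write_metrics_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
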