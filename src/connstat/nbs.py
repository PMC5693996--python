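"""Network-based statistics: permutation inference on connected components
of suprathreshold edges.

The procedure tests, for a two-group contrast, whether any connected
subnetwork of edges with group-difference t-statistics above an initial
threshold is larger than expected under exchangeability.  Family-wise
error is controlled through the permutation null distribution of the
maximum component size: group labels are randomly reassigned (keeping the
group sizes), the maximal suprathreshold component is recorded for each
relabelling, and each observed component's p-value is the fraction of the
null at least as large.  The observed labelling is counted as one
permutation, so the smallest attainable p is 1/N.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortDataset

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 4.20
DEFAULT_N_PERM = 10_000

_PERM_CHUNK = 512


@dataclass
class EdgeStatMap:
    """Edge-wise two-sample t statistics for one contrast."""

    t_values: np.ndarray            # N x N symmetric, zero diagonal
    region_labels: tuple[str, ...]
    df: int
    contrast: str = "group_b_minus_group_a"

    def condensed(self) -> np.ndarray:
        iu, ju = np.triu_indices(len(self.region_labels), k=1)
        return self.t_values[iu, ju]


@dataclass(frozen=True)
class Component:
    """A connected set of suprathreshold edges."""

    edges: frozenset
    nodes: frozenset
    size: int
    pvalue: float | None = None

    @classmethod
    def from_edges(cls, edges, pvalue: float | None = None) -> "Component":
        edges = frozenset(tuple(sorted(e)) for e in edges)
        nodes = frozenset(n for e in edges for n in e)
        return cls(edges=edges, nodes=nodes, size=len(edges), pvalue=pvalue)

    def with_pvalue(self, p: float) -> "Component":
        return Component(self.edges, self.nodes, self.size, p)


# ---------------------------------------------------------------------------
# Component machinery (union-find on the suprathreshold edge set)

def _component_edge_sets(edge_idx: np.ndarray, iu: np.ndarray,
                         ju: np.ndarray) -> list[list[int]]:
    """Group condensed edge indices into connected components."""
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for e in edge_idx:
        i, j = int(iu[e]), int(ju[e])
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        union(i, j)

    groups: dict[int, list[int]] = {}
    for e in edge_idx:
        root = find(int(iu[e]))
        groups.setdefault(root, []).append(int(e))
    return list(groups.values())


def _max_component_size(edge_idx: np.ndarray, iu: np.ndarray,
                        ju: np.ndarray) -> int:
    if edge_idx.size == 0:
        return 0
    return max(len(g) for g in _component_edge_sets(edge_idx, iu, ju))


def suprathreshold_components(stats: EdgeStatMap,
                              threshold: float) -> list[Component]:
    """Connected components of edges with t strictly above ``threshold``,
    sorted by size (descending), ties by smallest node label."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    n = len(stats.region_labels)
    iu, ju = np.triu_indices(n, k=1)
    above = np.flatnonzero(stats.condensed() > threshold)
    comps = []
    for group in _component_edge_sets(above, iu, ju):
        edges = [(stats.region_labels[iu[e]], stats.region_labels[ju[e]])
                 for e in group]
        comps.append(Component.from_edges(edges))
    comps.sort(key=lambda c: (-c.size, min(c.nodes)))
    return comps


def hub_detect(component: Component,
               n_total_nodes: int | None = None) -> set[str]:
    """Regions whose degree within the component exceeds the degree mean
    by more than two (sample) standard deviations.

    By default the mean and sd are taken over the component's own nodes;
    pass ``n_total_nodes`` to take them over the full network, counting
    regions not touched by the component as degree zero (isolated
    regions pull the mean down, which is how whole-brain hub reports are
    usually computed).
    """
    if component.size == 0:
        raise ValueError("component is empty")
    deg: dict[str, int] = {}
    for a, b in component.edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    values = list(deg.values())
    if n_total_nodes is not None:
        if n_total_nodes < len(deg):
            raise ValueError("n_total_nodes smaller than component node count")
        values = values + [0] * (n_total_nodes - len(deg))
    arr = np.asarray(values, dtype=float)
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    if sd == 0:
        return set()
    cutoff = arr.mean() + 2.0 * sd
    return {node for node, d in deg.items() if d > cutoff}


# ---------------------------------------------------------------------------
# t-statistic engine

def _group_t(x: np.ndarray, x2: np.ndarray, mask_b: np.ndarray,
             variance: str) -> np.ndarray:
    """t statistics (contrast b - a) for one or many relabellings.

    ``mask_b``: (P, S) 0/1 matrix of group-b membership; returns (P, E).
    """
    s_tot = x.sum(axis=0)
    q_tot = x2.sum(axis=0)
    nb = mask_b.sum(axis=1, keepdims=True)
    na = x.shape[0] - nb
    sb = mask_b @ x
    qb = mask_b @ x2
    sa = s_tot - sb
    qa = q_tot - qb
    var_a = (qa - sa**2 / na) / (na - 1)
    var_b = (qb - sb**2 / nb) / (nb - 1)
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    if variance == "pooled":
        sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    elif variance == "welch":
        se2 = var_a / na + var_b / nb
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    diff = sb / nb - sa / na
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    return np.where(se2 > 0, t, 0.0)


# ---------------------------------------------------------------------------
# Model / results

class NetworkBasedStatistic:
    """NBS model for a two-group contrast on a cohort of networks.

    Parameters
    ----------
    cohort : CohortDataset
        Cohort with built networks; all subjects share region ordering.
    group_a, group_b : str
        Group labels (``MDD_all`` pools the two patient groups).  The
        contrast is mean(group_b) - mean(group_a), i.e. positive t means
        higher connectivity in group_b.
    tail : {"greater", "two_sided"}
        Whether components are formed from t > threshold or |t| > threshold.
    variance : {"pooled", "welch"}
        Two-sample variance convention; pooled Student t is the classical
        NBS choice.
    """

    def __init__(self, cohort: CohortDataset, group_a: str, group_b: str,
                 tail: str = "greater", variance: str = "pooled"):
        if tail not in ("greater", "two_sided"):
            raise ValueError(f"unknown tail {tail!r}")
        if variance not in ("pooled", "welch"):
            raise ValueError(f"unknown variance mode {variance!r}")
        self.cohort = cohort
        self.group_a = group_a
        self.group_b = group_b
        self.tail = tail
        self.variance = variance

        mask_a = cohort.group_mask(group_a)
        mask_b = cohort.group_mask(group_b)
        if mask_a.sum() < 2:
            raise ValueError(f"group {group_a!r} has fewer than 2 subjects")
        if mask_b.sum() < 2:
            raise ValueError(f"group {group_b!r} has fewer than 2 subjects")
        if (mask_a & mask_b).any():
            raise ValueError("contrast groups overlap")
        if mask_a.sum() != mask_b.sum():
            logger.info(
                "unequal group sizes (%d vs %d); permutations keep the "
                "observed sizes", mask_a.sum(), mask_b.sum(),
            )
        sel = mask_a | mask_b
        self._x = cohort.edge_matrix()[sel]
        self._x2 = self._x**2
        self._is_b = mask_b[sel]
        self.n_a = int(mask_a.sum())
        self.n_b = int(mask_b.sum())
        self.region_labels = cohort.region_labels

    # -- statistics ---------------------------------------------------------

    def edge_tstats(self) -> EdgeStatMap:
        """Observed edge-wise two-sample t map (contrast b - a)."""
        t = _group_t(self._x, self._x2,
                     self._is_b[None, :].astype(float), self.variance)[0]
        n = len(self.region_labels)
        tm = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        tm[iu, ju] = t
        tm[ju, iu] = t
        return EdgeStatMap(
            t_values=tm, region_labels=self.region_labels,
            df=self.n_a + self.n_b - 2,
            contrast=f"{self.group_b}_minus_{self.group_a}",
        )

    def _tail_stat(self, t: np.ndarray) -> np.ndarray:
        return np.abs(t) if self.tail == "two_sided" else t

    def fit(self, threshold: float = DEFAULT_THRESHOLD,
            n_perm: int = DEFAULT_N_PERM, alpha: float = 0.05,
            seed: int | None = 0, exact: bool = False) -> "NBSResults":
        """Run the permutation test.

        With ``exact=True`` all distinct relabellings are enumerated
        (feasible for small cohorts) and the permutation p equals the
        exhaustive-enumeration p.
        """
        if not exact and n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

        stats = self.edge_tstats()
        observed = suprathreshold_components(
            EdgeStatMap(self._tail_stat(stats.t_values), self.region_labels,
                        stats.df, stats.contrast),
            threshold,
        )
        n = len(self.region_labels)
        iu, ju = np.triu_indices(n, k=1)
        s = self._x.shape[0]

        if exact:
            combos = list(itertools.combinations(range(s), self.n_b))
            masks = np.zeros((len(combos), s))
            for k, combo in enumerate(combos):
                masks[k, list(combo)] = 1.0
            null = self._null_sizes(masks, threshold, iu, ju)
            n_perm = len(combos)
        else:
            rng = np.random.default_rng(seed)
            null = np.empty(n_perm, dtype=int)
            null[0] = observed[0].size if observed else 0
            done = 1
            while done < n_perm:
                k = min(_PERM_CHUNK, n_perm - done)
                masks = np.zeros((k, s))
                for row in range(k):
                    masks[row, rng.permutation(s)[: self.n_b]] = 1.0
                null[done:done + k] = self._null_sizes(
                    masks, threshold, iu, ju)
                done += k

        components = []
        for comp in observed:
            p = float(np.count_nonzero(null >= comp.size)) / n_perm
            components.append(comp.with_pvalue(p))
        return NBSResults(
            model=self, stats=stats, components=components,
            null_max_sizes=np.asarray(null, dtype=int), threshold=threshold,
            n_perm=n_perm, alpha=alpha, seed=seed, exact=exact,
        )

    def _null_sizes(self, masks: np.ndarray, threshold: float,
                    iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
        t = self._tail_stat(
            _group_t(self._x, self._x2, masks, self.variance))
        above = t > threshold
        out = np.zeros(masks.shape[0], dtype=int)
        for row in np.flatnonzero(above.any(axis=1)):
            out[row] = _max_component_size(
                np.flatnonzero(above[row]), iu, ju)
        return out


@dataclass
class NBSResults:
    """Fitted NBS contrast: observed components, permutation null and
    per-component family-wise-corrected p-values."""

    model: NetworkBasedStatistic
    stats: EdgeStatMap
    components: list[Component]
    null_max_sizes: np.ndarray
    threshold: float
    n_perm: int
    alpha: float
    seed: int | None
    exact: bool = False

    @property
    def significant_components(self) -> list[Component]:
        return [c for c in self.components if c.pvalue <= self.alpha]

    def hubs(self, component: int = 0, scope: str = "parcellation") -> set[str]:
        """Hub regions of one component (default: the largest).

        ``scope="parcellation"`` computes the degree mean/sd over all
        regions of the parcellation (non-component regions at degree 0);
        ``scope="component"`` restricts them to the component's nodes.
        """
        if not self.components:
            return set()
        comp = self.components[component]
        if scope == "parcellation":
            return hub_detect(comp, n_total_nodes=len(self.model.region_labels))
        if scope == "component":
            return hub_detect(comp)
        raise ValueError(f"unknown scope {scope!r}")

    def edge_table(self, component: int = 0) -> pd.DataFrame:
        """Edge list of one component with t and per-group mean weights."""
        if not self.components:
            return pd.DataFrame(
                columns=["region_i", "region_j", "t", "mean_a", "mean_b"])
        comp = self.components[component]
        model = self.model
        labels = model.region_labels
        lut = {lab: k for k, lab in enumerate(labels)}
        t = self.stats.t_values
        iu, ju = np.triu_indices(len(labels), k=1)
        cond = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(iu, ju))}
        xa = model._x[~model._is_b]
        xb = model._x[model._is_b]
        rows = []
        for a, b in sorted(comp.edges):
            i, j = sorted((lut[a], lut[b]))
            e = cond[(i, j)]
            rows.append({
                "region_i": labels[i], "region_j": labels[j],
                "t": t[i, j],
                "mean_a": xa[:, e].mean(), "mean_b": xb[:, e].mean(),
            })
        return pd.DataFrame(rows,
                            columns=["region_i", "region_j", "t",
                                     "mean_a", "mean_b"])

    def to_dict(self) -> dict:
        return {
            "contrast": self.stats.contrast,
            "group_a": self.model.group_a,
            "group_b": self.model.group_b,
            "tail": self.model.tail,
            "variance": self.model.variance,
            "threshold": self.threshold,
            "n_perm": int(self.n_perm),
            "alpha": self.alpha,
            "seed": self.seed,
            "exact": self.exact,
            "df": int(self.stats.df),
            "components": [
                {
                    "edges": sorted(list(e) for e in c.edges),
                    "nodes": sorted(c.nodes),
                    "size": c.size,
                    "pvalue": c.pvalue,
                    "significant": bool(c.pvalue <= self.alpha),
                }
                for c in self.components
            ],
        }

    def summary(self) -> str:
        lines = [
            "Network-based statistics",
            "========================",
            f"contrast:   {self.stats.contrast} "
            f"({self.model.n_a} vs {self.model.n_b} subjects, "
            f"df={self.stats.df}, {self.model.variance} variance)",
            f"threshold:  t > {self.threshold:g} ({self.model.tail})",
            f"permutations: {self.n_perm}"
            + (" (exhaustive)" if self.exact else f" (seed {self.seed})"),
            f"alpha:      {self.alpha:g}",
            "",
            f"{'component':>9}  {'edges':>5}  {'regions':>7}  {'p':>8}",
        ]
        if not self.components:
            lines.append("  (no suprathreshold components)")
        for k, c in enumerate(self.components):
            star = " *" if c.pvalue <= self.alpha else ""
            lines.append(
                f"{k:>9}  {c.size:>5}  {len(c.nodes):>7}  "
                f"{c.pvalue:>8.4f}{star}"
            )
        sig = self.significant_components
        if sig:
            hubs = sorted(self.hubs(0)) if self.components else []
            lines += ["", f"hub regions (largest component): "
                          f"{', '.join(hubs) if hubs else 'none'}"]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers

def edgewise_t(cohort: CohortDataset, group_a: str, group_b: str,
               variance: str = "pooled") -> EdgeStatMap:
    """Edge-wise two-sample t map for the contrast b - a."""
    return NetworkBasedStatistic(
        cohort, group_a, group_b, variance=variance).edge_tstats()


def nbs_test(cohort: CohortDataset, group_a: str, group_b: str,
             threshold: float = DEFAULT_THRESHOLD,
             n_perm: int = DEFAULT_N_PERM, alpha: float = 0.05,
             seed: int | None = 0, tail: str = "greater",
             variance: str = "pooled", exact: bool = False) -> NBSResults:
    """One-call NBS permutation test (see :class:`NetworkBasedStatistic`)."""
    model = NetworkBasedStatistic(cohort, group_a, group_b, tail=tail,
                                  variance=variance)
    return model.fit(threshold=threshold, n_perm=n_perm, alpha=alpha,
                     seed=seed, exact=exact)
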