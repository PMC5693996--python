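"""ROI time series and non-negative Fisher-z functional connectivity networks.

A subject's resting-state signal is reduced to a T x N matrix of
region-averaged time courses.  The functional network is built in three
steps: pairwise Pearson correlation between regional time courses, the
variance-stabilizing Fisher transform z = atanh(r), and rectification —
self- and anti-correlations are discarded so the network carries only
positive weights, the space in which the weighted topology measures are
defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# atanh diverges at |r| = 1; correlations are clipped to this bound first
# so weights stay finite while the ordering of edges is preserved.
R_CLIP = 1.0 - 1e-7

_SYMMETRY_TOL = 1e-10


@dataclass
class RoiTimeSeries:
    """One subject's T x N matrix of ROI-averaged signals."""

    subject_id: str
    values: np.ndarray
    region_labels: tuple[str, ...]
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = tuple(self.region_labels)
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if n < 3:
            raise ValueError(f"need at least 3 regions, got {n}")
        if n != len(self.region_labels):
            raise ValueError("region_labels length does not match columns")
        if len(set(self.region_labels)) != n:
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FunctionalNetwork:
    """Symmetric non-negative N x N connectivity matrix in Fisher-z units."""

    subject_id: str
    weights: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.region_labels = tuple(self.region_labels)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.region_labels):
            raise ValueError("region_labels length does not match matrix")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        if np.abs(w - w.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("weights matrix is not symmetric")
        if np.abs(np.diagonal(w)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero")
        if w.min(initial=0.0) < 0:
            raise ValueError("weights must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def index_of(self, region: str) -> int:
        try:
            return self.region_labels.index(region)
        except ValueError:
            raise KeyError(
                f"region {region!r} not in network {self.subject_id!r}"
            ) from None


def pearson_matrix(ts: RoiTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlation between regional time courses.

    Returns the full N x N correlation matrix with unit diagonal.  A
    constant (zero-variance) regional signal has no defined correlation
    and raises, naming the offending region.
    """
    x = ts.values
    sd = x.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        names = ", ".join(ts.region_labels[i] for i in dead)
        raise ValueError(f"zero-variance time series in region(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r_matrix: np.ndarray) -> np.ndarray:
    """Elementwise Fisher r-to-z transform, z = atanh(r).

    Correlations are clipped to +/-(1 - 1e-7) before the transform so the
    result is always finite; the diagonal is set to zero (self-correlation
    carries no edge).
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.abs(r).max(initial=0.0) > 1.0:
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def rectify(
    z_matrix: np.ndarray,
    subject_id: str = "",
    region_labels: tuple[str, ...] | None = None,
) -> FunctionalNetwork:
    """Discard anti-correlations: negative z weights are set to zero.

    The diagonal is zeroed and the result is packaged as a
    :class:`FunctionalNetwork`.  Input must be symmetric to 1e-10.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("z matrix must be square")
    if np.abs(z - z.T).max(initial=0.0) > _SYMMETRY_TOL:
        raise ValueError("z matrix is asymmetric beyond tolerance 1e-10")
    w = np.where(z > 0, z, 0.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if region_labels is None:
        from .parcellation import generic_labels

        region_labels = generic_labels(z.shape[0])
    return FunctionalNetwork(subject_id, w, tuple(region_labels))


def build_network(ts: RoiTimeSeries) -> FunctionalNetwork:
    """Time series -> Pearson -> Fisher z -> rectified network."""
    r = pearson_matrix(ts)
    z = fisher_z(r)
    return rectify(z, subject_id=ts.subject_id, region_labels=ts.region_labels)


# ---------------------------------------------------------------------------
# Plain-text I/O: TSV with a header row of region labels.

def read_timeseries_tsv(
    path: str | Path,
    subject_id: str | None = None,
    tr_seconds: float = 3.0,
) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if subject_id is None:
        subject_id = path.stem
    return RoiTimeSeries(
        subject_id=subject_id,
        values=df.to_numpy(dtype=float),
        region_labels=tuple(df.columns),
        tr_seconds=tr_seconds,
    )


def write_timeseries_tsv(ts: RoiTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(ts.values, columns=list(ts.region_labels)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def read_adjacency_tsv(path: str | Path, subject_id: str | None = None) -> FunctionalNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if subject_id is None:
        subject_id = path.stem
    return FunctionalNetwork(
        subject_id=subject_id,
        weights=df.to_numpy(dtype=float),
        region_labels=tuple(df.columns),
    )


def write_adjacency_tsv(net: FunctionalNetwork, path: str | Path) -> Path:
    path = Path(path)
    labels = list(net.region_labels)
    pd.DataFrame(net.weights, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    return path


def write_edgelist_tsv(net: FunctionalNetwork, path: str | Path) -> Path:
    """Long-form upper-triangle edge list (region_i, region_j, z_weight)."""
    path = Path(path)
    n = net.n_regions
    iu, ju = np.triu_indices(n, k=1)
    df = pd.DataFrame(
        {
            "region_i": [net.region_labels[i] for i in iu],
            "region_j": [net.region_labels[j] for j in ju],
            "z_weight": net.weights[iu, ju],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
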