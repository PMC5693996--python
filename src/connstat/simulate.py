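"""Synthetic three-arm cohorts with planted connectivity effects.

The generator emulates the statistical structure of a case-control
resting-state study: two patient groups (depressed with and without
suicidal ideation, 23 each) plus healthy controls (36), 90-region
non-negative Fisher-z networks, a designated subnetwork whose edges carry
different group means, and clinical severity scores rank-coupled to the
subnetwork's total connectivity.  Two generation modes are provided:
direct edge-weight sampling (truncated Gaussian in z-space) and
multivariate-normal time series whose correlation targets are the nearest
positive-definite projection of the specified means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
from statsmodels.stats.correlation_tools import corr_nearest

from .cohort import MANIFEST_COLUMNS, CohortDataset
from .network import FunctionalNetwork, RoiTimeSeries
from .parcellation import AAL90_LABELS, canonicalize, generic_labels

# Instrument ranges for the generated integer scores.
SCORE_RANGES = {
    "suicidality": (0, 33),   # MINI suicidality module total
    "ssi": (0, 38),           # Scale for Suicide Ideation
    "ham_d": (0, 52),
    "ham_a": (0, 56),
    "mdq": (0, 13),
    "bis_motor": (11, 44),
    "bis_attention": (8, 32),
    "bis_nonplanning": (11, 44),
}

MALE_PROPORTION = 0.171  # cohort-wide male fraction being emulated


@dataclass(frozen=True)
class PlantedEffect:
    """A single edge with group-specific mean connectivity (z-units).

    ``mean_controls`` defaults to ``mean_group_b`` (the healthy-like
    level) when the cohort includes a control arm.
    """

    edge: tuple[str, str]
    mean_group_a: float
    mean_group_b: float
    mean_controls: float | None = None

    def __post_init__(self) -> None:
        a, b = self.edge
        if a == b:
            raise ValueError(f"planted edge endpoints must differ: {a!r}")
        for m in (self.mean_group_a, self.mean_group_b):
            if not math.isfinite(m):
                raise ValueError("planted means must be finite")

    @property
    def control_mean(self) -> float:
        return (self.mean_group_b if self.mean_controls is None
                else self.mean_controls)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``background_sd`` spreads the latent per-edge means around
    ``background_mean`` (shared by all groups, so unplanted edges are
    exchangeable); ``edge_sd`` is the subject-to-subject spread around an
    edge's mean.  ``score_coupling`` is the target population Spearman
    correlation between each severity score and the summed planted-edge
    weight (negative: weaker connectivity, worse score).
    """

    n_group_a: int = 23              # SI
    n_group_b: int = 23              # noSI
    n_controls: int = 36             # HC
    n_regions: int = 90
    background_mean: float = 0.4
    background_sd: float = 0.1
    edge_sd: float = 0.1
    planted: tuple[PlantedEffect, ...] = ()
    n_timepoints: int = 200          # at TR 3 s: a 10-minute scan
    score_coupling: float = -0.5
    covariate_ranges: dict = field(default_factory=lambda: {
        "age": (45, 68), "education_years": (6, 22)})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a <= 0 or self.n_group_b <= 0 or self.n_controls < 0:
            raise ValueError("group sizes must be positive (controls >= 0)")
        if self.n_regions < 3:
            raise ValueError("n_regions must be at least 3")
        if self.background_sd < 0 or self.edge_sd <= 0:
            raise ValueError("sds must be positive (background_sd >= 0)")
        if abs(self.score_coupling) > 1:
            raise ValueError("|score_coupling| must be <= 1")
        self.planted = tuple(self.planted)

    @property
    def region_labels(self) -> tuple[str, ...]:
        if self.n_regions == len(AAL90_LABELS):
            return AAL90_LABELS
        return generic_labels(self.n_regions)

    def resolved_planted(self) -> list[tuple[int, int, PlantedEffect]]:
        """Planted effects with canonical (i, j) index pairs, i < j."""
        labels = self.region_labels
        lut = {lab: k for k, lab in enumerate(labels)}
        out = []
        for eff in self.planted:
            idx = []
            for name in eff.edge:
                key = canonicalize(name) if labels is AAL90_LABELS else name
                if key not in lut:
                    raise KeyError(
                        f"planted edge region {name!r} not in parcellation"
                    )
                idx.append(lut[key])
            i, j = sorted(idx)
            out.append((i, j, eff))
        return out


def fronto_thalamic_subnetwork() -> tuple[PlantedEffect, ...]:
    """Reference planted-effect template: the 11-edge orbitofrontal-
    thalamic subnetwork reported to carry reduced connectivity in
    depressed patients with suicidal ideation, with the published
    per-group mean z connectivities (group a = with ideation, group b =
    without).
    """
    rows = [
        (("Frontal_Sup_Orb_L", "Caudate_L"), 0.29, 0.52),
        (("Frontal_Sup_Orb_L", "Caudate_R"), 0.27, 0.48),
        (("Frontal_Sup_Orb_L", "Olfactory_R"), 0.19, 0.40),
        (("Frontal_Sup_Orb_L", "Putamen_R"), 0.11, 0.33),
        (("Thalamus_L", "Frontal_Sup_Orb_L"), 0.10, 0.32),
        (("Thalamus_L", "Frontal_Mid_Orb_L"), 0.13, 0.35),
        (("Thalamus_L", "Temporal_Mid_L"), 0.34, 0.54),
        (("Thalamus_R", "Frontal_Sup_Orb_L"), 0.061, 0.29),
        (("Thalamus_R", "Frontal_Mid_Orb_L"), 0.084, 0.32),
        (("Thalamus_R", "Temporal_Mid_L"), 0.24, 0.51),
        (("Thalamus_R", "Postcentral_L"), 0.20, 0.49),
    ]
    return tuple(PlantedEffect(edge, a, b) for edge, a, b in rows)


# ---------------------------------------------------------------------------
# Internal helpers

def _condensed_index(i: int, j: int, n: int) -> int:
    """Position of edge (i, j), i < j, in the upper-triangle vector."""
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def _group_vector(spec: CohortSpec) -> np.ndarray:
    return np.array(
        ["SI"] * spec.n_group_a + ["noSI"] * spec.n_group_b
        + ["HC"] * spec.n_controls
    )


def _base_manifest(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    groups = _group_vector(spec)
    n = len(groups)
    ids = [f"sub-{k + 1:03d}" for k in range(n)]
    lo_age, hi_age = spec.covariate_ranges["age"]
    lo_edu, hi_edu = spec.covariate_ranges["education_years"]
    age = rng.integers(lo_age, hi_age + 1, size=n)
    gender = (rng.random(n) < MALE_PROPORTION).astype(int)
    education = np.clip(
        np.rint(rng.normal(11.6, 4.3, size=n)), lo_edu, hi_edu
    ).astype(int)
    df = pd.DataFrame({
        "subject_id": ids,
        "group": groups,
        "age": age,
        "gender": gender,
        "education_years": education,
    })
    for col in MANIFEST_COLUMNS[5:]:
        df[col] = np.nan
    return df.set_index("subject_id")


def _edge_mean_matrix(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-group condensed mean vectors, stacked (3, E) as SI/noSI/HC."""
    n = spec.n_regions
    n_edges = n * (n - 1) // 2
    mu_bg = spec.background_mean + spec.background_sd * rng.standard_normal(n_edges)
    mu = np.tile(mu_bg, (3, 1))
    for i, j, eff in spec.resolved_planted():
        e = _condensed_index(i, j, n)
        mu[0, e] = eff.mean_group_a
        mu[1, e] = eff.mean_group_b
        mu[2, e] = eff.control_mean
    return mu


def _to_networks(
    x: np.ndarray, ids: list[str], labels: tuple[str, ...]
) -> list[FunctionalNetwork]:
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    nets = []
    for row, sid in zip(x, ids):
        w = np.zeros((n, n))
        w[iu, ju] = row
        w[ju, iu] = row
        nets.append(FunctionalNetwork(sid, w, labels))
    return nets


# ---------------------------------------------------------------------------
# Generators

def generate_edge_cohort(spec: CohortSpec) -> CohortDataset:
    """Sample subject networks directly in edge space.

    Every unplanted edge shares one latent mean across groups; planted
    edges take their group means.  Subject weights are Gaussian around
    the edge mean (sd ``edge_sd``) truncated at zero, matching the
    rectified non-negative network space.  Deterministic given the spec
    (including its seed).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_cov, rng_edges = (np.random.default_rng(c) for c in ss.spawn(2))
    manifest = _base_manifest(spec, rng_cov)
    groups = manifest["group"].to_numpy()
    mu = _edge_mean_matrix(spec, rng_edges)
    gidx = np.array([{"SI": 0, "noSI": 1, "HC": 2}[g] for g in groups])
    n_edges = mu.shape[1]
    noise = rng_edges.standard_normal((len(groups), n_edges))
    x = np.maximum(mu[gidx] + spec.edge_sd * noise, 0.0)
    nets = _to_networks(x, list(manifest.index), spec.region_labels)
    return CohortDataset(manifest, networks=nets)


def _nearest_correlation(r: np.ndarray, tol: float = 1e-8,
                         max_iter: int = 100) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite
    correlation matrix (Higham-style alternating projections).

    Already-PD inputs are returned unchanged; otherwise the projection
    runs for at most ``max_iter`` sweeps and the result is required to be
    positive definite.
    """
    r = np.asarray((r + r.T) / 2.0)
    if np.linalg.eigvalsh(r).min() >= tol:
        return r
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = corr_nearest(r, threshold=tol, n_fact=max_iter)
    out = np.asarray((out + out.T) / 2.0)
    eigmin = np.linalg.eigvalsh(out).min()
    if eigmin <= 0:
        raise RuntimeError(
            "nearest-correlation projection failed to reach positive "
            f"definiteness after {max_iter} iterations "
            f"(min eigenvalue {eigmin:.2e})"
        )
    return out


def generate_timeseries_cohort(spec: CohortSpec) -> CohortDataset:
    """Sample per-subject T x N series from zero-mean multivariate
    normals whose correlation matrix is the nearest positive-definite
    projection of the group target (r = tanh of the specified z means).
    """
    if spec.n_timepoints < 30:
        raise ValueError("n_timepoints must be at least 30")
    ss = np.random.SeedSequence(spec.seed)
    rng_cov, rng_edges, rng_ts = (np.random.default_rng(c) for c in ss.spawn(3))
    manifest = _base_manifest(spec, rng_cov)
    groups = manifest["group"].to_numpy()
    mu = _edge_mean_matrix(spec, rng_edges)

    n = spec.n_regions
    iu, ju = np.triu_indices(n, k=1)
    chols = {}
    for gname, row in zip(("SI", "noSI", "HC"), mu):
        r = np.eye(n)
        r[iu, ju] = np.tanh(row)
        r[ju, iu] = np.tanh(row)
        r_pd = _nearest_correlation(r)
        # tiny jitter keeps the factorization stable at eigenvalues ~1e-8
        chols[gname] = np.linalg.cholesky(r_pd + 1e-10 * np.eye(n))

    series = []
    for sid, g in zip(manifest.index, groups):
        z = rng_ts.standard_normal((spec.n_timepoints, n))
        series.append(RoiTimeSeries(sid, z @ chols[g].T, spec.region_labels))
    return CohortDataset(manifest, timeseries=series)


def _round_away(v: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def _integer_score(latent: np.ndarray, center: float, scale: float,
                   lo: int, hi: int) -> np.ndarray:
    return np.clip(_round_away(center + scale * latent), lo, hi).astype(int)


def generate_clinical_scores(dataset: CohortDataset,
                             spec: CohortSpec) -> CohortDataset:
    """Fill the manifest's score columns.

    Suicidality and SSI are generated, for the patient subjects, from a
    Gaussian copula on the (negated) summed planted-edge weight: the
    latent severity is ``rho_p * z_x + sqrt(1 - rho_p^2) * noise`` with
    ``rho_p = 2 sin(pi * score_coupling / 6)``, which gives the requested
    population Spearman correlation exactly; integer discretization to
    the instrument range happens after calibration.  The depression,
    anxiety and impulsivity scales are uncoupled noise (their null
    association is part of the emulated structure), and controls receive
    low-range noise scores.
    """
    if abs(spec.score_coupling) == 1:
        raise ValueError(
            "unsatisfiable: |score_coupling| = 1 cannot be met with "
            "nonzero score noise"
        )
    if not dataset.networks:
        raise ValueError("dataset has no networks; build them before scores")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    manifest = dataset.manifest.copy()
    mdd = dataset.group_mask("MDD_all")
    n_mdd = int(mdd.sum())

    planted = spec.resolved_planted()
    x = dataset.edge_matrix()
    if planted:
        n = spec.n_regions
        cols = [_condensed_index(i, j, n) for i, j, _ in planted]
        subnet = x[:, cols].sum(axis=1)
    else:
        subnet = x.sum(axis=1)

    # normal scores of the patient subnetwork weights
    ranks = rankdata(subnet[mdd])
    zx = ndtri((ranks - 0.5) / n_mdd)
    rho_p = 2.0 * math.sin(math.pi * spec.score_coupling / 6.0)
    mix = math.sqrt(1.0 - rho_p ** 2)

    def coupled(center: float, scale: float, lo: int, hi: int) -> np.ndarray:
        latent = rho_p * zx + mix * rng.standard_normal(n_mdd)
        return _integer_score(latent, center, scale, lo, hi)

    suicidality = np.zeros(dataset.n_subjects, dtype=int)
    ssi = np.zeros(dataset.n_subjects, dtype=int)
    suicidality[mdd] = coupled(10.0, 7.0, *SCORE_RANGES["suicidality"])
    ssi[mdd] = coupled(14.0, 8.0, *SCORE_RANGES["ssi"])
    hc = ~mdd
    n_hc = int(hc.sum())
    ssi[hc] = _integer_score(rng.standard_normal(n_hc), 1.5, 1.5, 0, 6)

    manifest["suicidality"] = suicidality
    manifest["ssi"] = ssi

    uncoupled = {
        "ham_d": (19.5, 3.0), "ham_a": (17.0, 4.5), "mdq": (4.2, 3.3),
        "bis_motor": (15.8, 3.9), "bis_attention": (15.9, 3.2),
        "bis_nonplanning": (20.1, 5.2),
    }
    for col, (center, scale) in uncoupled.items():
        lo, hi = SCORE_RANGES[col]
        vals = np.zeros(dataset.n_subjects, dtype=int)
        vals[mdd] = _integer_score(rng.standard_normal(n_mdd),
                                   center, scale, lo, hi)
        vals[hc] = _integer_score(rng.standard_normal(n_hc),
                                  max(lo, 2.0), 1.5, lo, min(hi, lo + 7))
        manifest[col] = vals

    return CohortDataset(manifest, networks=dataset.networks,
                         timeseries=dataset.timeseries)


def write_cohort(dataset: CohortDataset, outdir, spec: CohortSpec | None = None,
                 mode: str = "edges") -> None:
    """Write a cohort to disk: manifest CSV, one TSV per subject
    (adjacency or time-series), and a sidecar YAML recording the
    generating spec and seed when one is given."""
    from pathlib import Path

    import yaml

    from .cohort import write_manifest
    from .network import write_adjacency_tsv, write_timeseries_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_manifest(dataset.manifest, outdir / "manifest.csv")
    subj_dir = outdir / "subjects"
    subj_dir.mkdir(exist_ok=True)
    if mode == "edges":
        for net in dataset.networks:
            write_adjacency_tsv(net, subj_dir / f"{net.subject_id}.tsv")
    else:
        for ts in dataset.timeseries:
            write_timeseries_tsv(ts, subj_dir / f"{ts.subject_id}.tsv")
    if spec is not None:
        payload = {
            "seed": spec.seed,
            "mode": mode,
            "n_group_a": spec.n_group_a,
            "n_group_b": spec.n_group_b,
            "n_controls": spec.n_controls,
            "n_regions": spec.n_regions,
            "background_mean": spec.background_mean,
            "background_sd": spec.background_sd,
            "edge_sd": spec.edge_sd,
            "n_timepoints": spec.n_timepoints,
            "score_coupling": spec.score_coupling,
            "planted": [
                {"edge": list(e.edge), "mean_group_a": e.mean_group_a,
                 "mean_group_b": e.mean_group_b,
                 "mean_controls": e.mean_controls}
                for e in spec.planted
            ],
        }
        (outdir / "spec.yaml").write_text(yaml.safe_dump(payload))


def generate_cohort(spec: CohortSpec, mode: str = "edges") -> CohortDataset:
    """Convenience: generate networks (directly or via time series) and
    clinical scores in one call."""
    if mode == "edges":
        ds = generate_edge_cohort(spec)
    elif mode == "timeseries":
        from .network import build_network

        ds = generate_timeseries_cohort(spec)
        ds = ds.with_networks([build_network(ts) for ts in ds.timeseries])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return generate_clinical_scores(ds, spec)
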