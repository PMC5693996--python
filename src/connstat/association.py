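"""Covariate-controlled rank correlation of connectivity with severity.

Edge weights (or hub nodal metrics) are correlated with clinical scores
using partial Spearman correlation: every variable is rank-transformed,
the covariates (age, gender, education years) are regressed out of both
rank vectors by least squares, and the correlation of the residuals is
tested on n - 2 - k degrees of freedom.  Multiplicity within each family
(all edges of the subnetwork for one score; all hub-metric pairs for one
score) is handled by Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import COVARIATE_COLUMNS, MDD_ALL, CohortDataset
from .nbs import Component
from .topology import METRIC_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_SCORES = ("suicidality", "ssi")

ASSOCIATION_COLUMNS = ("feature", "score", "rho", "p", "p_fdr", "n",
                       "family", "valid")


def spearman_partial(x: np.ndarray, y: np.ndarray,
                     covariates: np.ndarray | None = None
                     ) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks on ties); covariate
    effects are removed from both rank vectors by least squares with an
    intercept; rho is the Pearson correlation of the residuals.  The
    p-value uses t = rho * sqrt((n - 2 - k) / (1 - rho^2)) on n - 2 - k
    degrees of freedom, two-sided.  With no covariates this is exactly
    the ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in x or y")
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise ValueError("covariate rows must match x length")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite values in covariates")
    k = z.shape[1]
    if n < k + 4:
        raise ValueError(f"need at least k + 4 = {k + 4} observations")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0:
        raise ValueError("x is constant after ranking")
    if np.ptp(ry) == 0:
        raise ValueError("y is constant after ranking")

    design = np.column_stack([np.ones(n)] +
                             [sps.rankdata(z[:, c]) for c in range(k)])
    coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ coef_x
    ey = ry - design @ coef_y

    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        raise ValueError("residuals are degenerate (constant after "
                         "covariate adjustment)")
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return rho, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _subject_frame(cohort: CohortDataset, subjects: str) -> pd.DataFrame:
    mask = cohort.group_mask(subjects)
    frame = cohort.manifest.loc[mask].copy()
    missing = frame[list(COVARIATE_COLUMNS)].isna().any(axis=1)
    if missing.any():
        for sid in frame.index[missing]:
            logger.warning("dropping subject %s: missing covariate(s)", sid)
        frame = frame.loc[~missing]
    if len(frame) < 10:
        raise ValueError(
            f"only {len(frame)} subjects with complete covariates; "
            "need at least 10 for association analysis"
        )
    return frame


def _run_family(features: dict[str, np.ndarray], scores_frame: pd.DataFrame,
                covariates: np.ndarray, score_names,
                family_prefix: str) -> pd.DataFrame:
    rows = []
    for score in score_names:
        y = scores_frame[score].to_numpy(dtype=float)
        family = f"{family_prefix}:{score}"
        for feat, x in features.items():
            try:
                rho, p = spearman_partial(x, y, covariates)
                rows.append({"feature": feat, "score": score, "rho": rho,
                             "p": p, "n": x.size, "family": family,
                             "valid": True})
            except ValueError as exc:
                logger.warning("association %s ~ %s invalid: %s",
                               feat, score, exc)
                rows.append({"feature": feat, "score": score, "rho": np.nan,
                             "p": np.nan, "n": x.size, "family": family,
                             "valid": False})
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    for family, idx in table.groupby("family").groups.items():
        sub = table.loc[idx]
        ok = sub["valid"] & sub["p"].notna()
        if ok.any():
            table.loc[sub.index[ok], "p_fdr"] = bh_fdr(
                sub.loc[ok, "p"].to_numpy())
    return table[list(ASSOCIATION_COLUMNS)]


def associate_edges(cohort: CohortDataset, component: Component,
                    scores=DEFAULT_SCORES,
                    subjects: str = MDD_ALL) -> pd.DataFrame:
    """Partial Spearman association of each component edge's weight with
    each clinical score, FDR-corrected per score across the component's
    edges.  Run on the pooled patient sample by default."""
    frame = _subject_frame(cohort, subjects)
    pos = [cohort.subject_ids.index(s) for s in frame.index]
    covariates = frame[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    features = {}
    for a, b in sorted(component.edges):
        features[f"{a}--{b}"] = cohort.edge_weights(a, b)[pos]
    return _run_family(features, frame, covariates, scores, "edges")


def associate_metrics(cohort: CohortDataset, hubs, metrics: pd.DataFrame,
                      scores=DEFAULT_SCORES, subjects: str = MDD_ALL,
                      family_mode: str = "per_score") -> pd.DataFrame:
    """Partial Spearman association of each (hub region, nodal metric)
    with each clinical score.

    ``family_mode="per_score"`` corrects over all hub-metric pairs within
    one score; ``"per_metric"`` corrects within each metric separately.
    """
    if family_mode not in ("per_score", "per_metric"):
        raise ValueError(f"unknown family_mode {family_mode!r}")
    if not hubs:
        return pd.DataFrame(columns=list(ASSOCIATION_COLUMNS))
    frame = _subject_frame(cohort, subjects)
    covariates = frame[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    wide = metrics.set_index(["subject_id", "region"])
    tables = []
    if family_mode == "per_score":
        features = {}
        for region in sorted(hubs):
            for metric in METRIC_COLUMNS:
                vals = wide.loc[[(s, region) for s in frame.index], metric]
                features[f"{region}:{metric}"] = vals.to_numpy(dtype=float)
        tables.append(_run_family(features, frame, covariates, scores,
                                  "hub_metrics"))
    else:
        for metric in METRIC_COLUMNS:
            features = {
                f"{region}:{metric}": wide.loc[
                    [(s, region) for s in frame.index], metric
                ].to_numpy(dtype=float)
                for region in sorted(hubs)
            }
            tables.append(_run_family(features, frame, covariates, scores,
                                      f"hub_metrics[{metric}]"))
    return pd.concat(tables, ignore_index=True)


def write_association_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
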