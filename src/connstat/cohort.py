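"""Cohort container: aligned networks, group labels, covariates and scores.

Groups follow the three-arm case-control design this package targets:
depressed patients with suicidal ideation (``SI``), depressed patients
without (``noSI``), and healthy controls (``HC``).  The pseudo-group
``MDD_all`` denotes the pooled patient sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import FunctionalNetwork, RoiTimeSeries

GROUP_LABELS = ("SI", "noSI", "HC")
MDD_ALL = "MDD_all"

MANIFEST_COLUMNS = (
    "subject_id", "group", "age", "gender", "education_years",
    "suicidality", "ssi", "ham_d", "ham_a", "mdq",
    "bis_motor", "bis_attention", "bis_nonplanning",
)

COVARIATE_COLUMNS = ("age", "gender", "education_years")
SCORE_COLUMNS = ("suicidality", "ssi", "ham_d", "ham_a", "mdq",
                 "bis_motor", "bis_attention", "bis_nonplanning")


@dataclass
class CohortDataset:
    """Aligned collection of subject networks (or time series) with the
    cohort manifest.

    ``manifest`` is indexed by ``subject_id`` and carries ``group``, the
    covariates (age, gender, education_years) and the clinical scores.
    ``networks``/``timeseries`` lists are aligned with the manifest rows.
    """

    manifest: pd.DataFrame
    networks: list[FunctionalNetwork] | None = None
    timeseries: list[RoiTimeSeries] | None = None

    def __post_init__(self) -> None:
        if self.manifest.index.name != "subject_id":
            raise ValueError("manifest must be indexed by subject_id")
        if self.manifest.index.duplicated().any():
            dup = self.manifest.index[self.manifest.index.duplicated()][0]
            raise ValueError(f"duplicate subject id: {dup!r}")
        bad = set(self.manifest["group"]) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        for coll, name in ((self.networks, "networks"),
                           (self.timeseries, "timeseries")):
            if coll is None:
                continue
            if len(coll) != len(self.manifest):
                raise ValueError(f"{name} not aligned with manifest")
            labels = coll[0].region_labels
            for item in coll:
                if item.region_labels != labels:
                    raise ValueError(
                        "all subjects must share the same region ordering"
                    )

    # -- basic views --------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.manifest)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.manifest.index)

    @property
    def region_labels(self) -> tuple[str, ...]:
        if self.networks:
            return self.networks[0].region_labels
        if self.timeseries:
            return self.timeseries[0].region_labels
        raise ValueError("cohort carries neither networks nor time series")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask over subjects; ``MDD_all`` pools SI and noSI."""
        g = self.manifest["group"].to_numpy()
        if group == MDD_ALL:
            return (g == "SI") | (g == "noSI")
        if group not in GROUP_LABELS:
            raise KeyError(f"unknown group label: {group!r}")
        return g == group

    # -- edge-vector view ----------------------------------------------------

    def triu_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_regions, k=1)

    def edge_pairs(self) -> list[tuple[str, str]]:
        """Upper-triangle (region_i, region_j) pairs in condensed order."""
        labels = self.region_labels
        iu, ju = self.triu_indices()
        return [(labels[i], labels[j]) for i, j in zip(iu, ju)]

    def edge_matrix(self) -> np.ndarray:
        """Subjects x edges matrix of condensed upper-triangle weights."""
        if not self.networks:
            raise ValueError("cohort has no networks; build them first")
        iu, ju = self.triu_indices()
        return np.stack([net.weights[iu, ju] for net in self.networks])

    def edge_weights(self, region_a: str, region_b: str) -> np.ndarray:
        """Per-subject weight of one edge."""
        if not self.networks:
            raise ValueError("cohort has no networks; build them first")
        i = self.networks[0].index_of(region_a)
        j = self.networks[0].index_of(region_b)
        return np.array([net.weights[i, j] for net in self.networks])

    def with_networks(self, networks: list[FunctionalNetwork]) -> "CohortDataset":
        return CohortDataset(self.manifest, networks=networks,
                             timeseries=self.timeseries)


# ---------------------------------------------------------------------------
# Manifest I/O

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Required columns are ``subject_id``, ``group`` and the covariates;
    score columns are optional but recommended.  Errors name the row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"no records in manifest {path}")
    required = ("subject_id", "group") + COVARIATE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing column(s): {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        row = dup.index[0] + 2  # header + 1-based
        raise ValueError(
            f"duplicate subject id {dup.iloc[0]!r} (row {row})"
        )
    bad = df[~df["group"].isin(GROUP_LABELS)]
    if not bad.empty:
        row = bad.index[0] + 2
        raise ValueError(
            f"unknown group {bad['group'].iloc[0]!r} (row {row}); "
            f"expected one of {GROUP_LABELS}"
        )
    return df.set_index("subject_id")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=True)
    return path
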