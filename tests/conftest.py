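import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import connstat as cs

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_cohort(edge_values: dict, groups: list[str],
                region_labels: tuple[str, ...],
                fill: float = 0.0) -> cs.CohortDataset:
    """Build a cohort from explicit per-edge subject values.

    ``edge_values`` maps (region_a, region_b) -> sequence of per-subject
    weights; all other edges take ``fill``.
    """
    n = len(region_labels)
    idx = {lab: i for i, lab in enumerate(region_labels)}
    s = len(groups)
    nets = []
    for k in range(s):
        w = np.full((n, n), fill, dtype=float)
        np.fill_diagonal(w, 0.0)
        for (a, b), vals in edge_values.items():
            w[idx[a], idx[b]] = vals[k]
            w[idx[b], idx[a]] = vals[k]
        nets.append(cs.FunctionalNetwork(f"sub-{k:03d}", w, region_labels))
    manifest = pd.DataFrame({
        "subject_id": [f"sub-{k:03d}" for k in range(s)],
        "group": groups,
        "age": 50, "gender": 0, "education_years": 12,
    }).set_index("subject_id")
    return cs.CohortDataset(manifest, networks=nets)


def random_network(rng: np.random.Generator, n: int,
                   density: float = 0.5) -> cs.FunctionalNetwork:
    """Random weighted network with continuous weights (no ties)."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    w[iu[present], ju[present]] = rng.uniform(0.05, 1.0, present.sum())
    w = w + w.T
    return cs.FunctionalNetwork("rand", w, cs.parcellation.generic_labels(n))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
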