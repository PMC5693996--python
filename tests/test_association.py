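"""Partial Spearman association and FDR adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

import connstat as cs
from connstat.association import associate_edges, associate_metrics, bh_fdr


class TestSpearmanPartial:
    def test_reduces_to_plain_spearman_without_covariates(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        rho, p = cs.spearman_partial(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        z = rng.normal(size=(25, 2))
        rho1, _ = cs.spearman_partial(x, y, z)
        rho2, _ = cs.spearman_partial(np.exp(3 * x), y, z)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_matches_independent_implementation(self, rng):
        # pingouin computes partial Spearman through an entirely separate
        # code path (correlation-matrix inversion)
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        z = rng.normal(size=(20, 3))
        rho, p = cs.spearman_partial(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "c1": z[:, 0], "c2": z[:, 1],
                           "c3": z[:, 2]})
        ref = pingouin.partial_corr(df, x="x", y="y",
                                    covar=["c1", "c2", "c3"],
                                    method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(400):
            x = rng.normal(size=46)
            y = rng.normal(size=46)
            z = rng.normal(size=(46, 3))
            pvals.append(cs.spearman_partial(x, y, z)[1])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 1e-3

    @pytest.mark.parametrize("bad_x", [np.ones(20), np.full(20, np.nan)])
    def test_degenerate_inputs_rejected(self, bad_x, rng):
        y = rng.normal(size=20)
        with pytest.raises(ValueError):
            cs.spearman_partial(bad_x, y)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            cs.spearman_partial(rng.normal(size=6), rng.normal(size=6),
                                rng.normal(size=(6, 3)))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_hand_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_original_order_preserved(self):
        out = bh_fdr([0.04, 0.01, 0.03, 0.02])
        assert np.allclose(out, 0.04)
        out2 = bh_fdr([0.5, 0.001])
        assert out2[1] < out2[0]

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=20))
    def test_dominance_and_bound(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


def coupled_cohort(seed=0, coupling=-0.5):
    spec = cs.CohortSpec(
        n_group_a=23, n_group_b=23, n_controls=0, n_regions=8,
        background_sd=0.0, edge_sd=0.1, score_coupling=coupling, seed=seed,
        planted=(cs.PlantedEffect(("roi_00", "roi_01"), 0.10, 0.35),
                 cs.PlantedEffect(("roi_01", "roi_02"), 0.15, 0.40),
                 cs.PlantedEffect(("roi_03", "roi_04"), 0.20, 0.45)),
    )
    comp = cs.Component.from_edges([e.edge for e in spec.planted])
    return cs.generate_cohort(spec), comp, spec


class TestAssociateEdges:
    def test_table_structure_and_families(self):
        cohort, comp, _ = coupled_cohort()
        table = associate_edges(cohort, comp)
        assert len(table) == 3 * 2  # 3 edges x 2 scores
        assert set(table["score"]) == {"suicidality", "ssi"}
        assert (table["p_fdr"] >= table["p"] - 1e-15).all()
        assert (table["n"] == 46).all()
        # FDR families are per score across edges
        assert table.groupby("family").size().eq(3).all()

    def test_planted_negative_coupling_recovered(self):
        rhos = []
        for seed in range(30):
            cohort, comp, _ = coupled_cohort(seed=seed)
            table = associate_edges(cohort, comp, scores=("suicidality",))
            w = np.array([
                cohort.edge_weights(*f.split("--"))
                for f in table["feature"]
            ])
            rhos.extend(table["rho"])
            sig = table[table["p_fdr"] < 0.05]
            assert (sig["rho"] < 0).all()
        # each edge carries roughly 1/3 of the coupled signal
        assert np.mean(rhos) < -0.2

    def test_null_coupling_calibration(self):
        hits = 0
        total = 0
        for seed in range(25):
            cohort, comp, _ = coupled_cohort(seed=seed, coupling=0.0)
            table = associate_edges(cohort, comp)
            hits += (table["p"] < 0.05).sum()
            total += len(table)
        # ~5% raw rejections under the null, +/- 3 binomial sd
        assert hits / total < 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_missing_covariates_drop_subjects(self, caplog):
        cohort, comp, _ = coupled_cohort()
        cohort.manifest.loc[cohort.subject_ids[0], "age"] = np.nan
        table = associate_edges(cohort, comp)
        assert (table["n"] == 45).all()

    def test_too_few_subjects_rejected(self):
        cohort, comp, _ = coupled_cohort()
        cohort.manifest.loc[cohort.subject_ids[8:], "age"] = np.nan
        with pytest.raises(ValueError, match="at least 10"):
            associate_edges(cohort, comp)


class TestAssociateMetrics:
    def test_empty_hub_set_gives_empty_table(self):
        cohort, comp, _ = coupled_cohort()
        metrics = cs.compute_all(cohort)
        table = associate_metrics(cohort, set(), metrics)
        assert table.empty

    def test_rows_per_hub_metric_score(self):
        cohort, comp, _ = coupled_cohort()
        metrics = cs.compute_all(cohort)
        table = associate_metrics(cohort, {"roi_00", "roi_01"}, metrics)
        assert len(table) == 2 * 4 * 2  # hubs x metrics x scores
        assert table.groupby("family").size().eq(8).all()

    def test_per_metric_family_mode(self):
        cohort, comp, _ = coupled_cohort()
        metrics = cs.compute_all(cohort)
        table = associate_metrics(cohort, {"roi_00", "roi_01"}, metrics,
                                  family_mode="per_metric")
        assert table.groupby("family").size().eq(2).all()

    def test_constant_metric_marked_invalid(self):
        cohort, comp, _ = coupled_cohort()
        metrics = cs.compute_all(cohort)
        metrics.loc[metrics["region"] == "roi_00", "betweenness"] = 0.0
        table = associate_metrics(cohort, {"roi_00"}, metrics)
        bad = table[table["feature"] == "roi_00:betweenness"]
        assert (~bad["valid"]).all()
        assert bad["rho"].isna().all()
        good = table[table["valid"]]
        assert good["p_fdr"].notna().all()

    def test_hub_strength_tracks_negative_coupling(self):
        # hub strength aggregates the planted edges, so its association
        # with severity should be negative and strong
        cohort, comp, _ = coupled_cohort(seed=4)
        metrics = cs.compute_all(cohort)
        table = associate_metrics(cohort, {"roi_01"}, metrics,
                                  scores=("suicidality",))
        rho = table.loc[table["feature"] == "roi_01:strength", "rho"].iloc[0]
        assert rho < -0.2
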