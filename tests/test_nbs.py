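"""NBS engine: edge t statistics, components, permutation p, hubs."""

import numpy as np
import pytest

import connstat as cs
from _oracles import components_by_networkx, exact_nbs_pvalue
from connstat.nbs import EdgeStatMap, hub_detect, suprathreshold_components
from connstat.parcellation import generic_labels
from conftest import make_cohort


def stat_map(edges_with_t: dict, labels: tuple[str, ...]) -> EdgeStatMap:
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    t = np.zeros((n, n))
    for (a, b), v in edges_with_t.items():
        t[idx[a], idx[b]] = v
        t[idx[b], idx[a]] = v
    return EdgeStatMap(t_values=t, region_labels=labels, df=10)


class TestEdgewiseT:
    def test_identical_groups_give_zero(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        cohort = make_cohort({("roi_00", "roi_01"): vals},
                             ["SI"] * 3 + ["noSI"] * 3, generic_labels(4))
        t = cs.edgewise_t(cohort, "SI", "noSI")
        assert np.all(t.t_values == 0)

    def test_hand_computed_t(self):
        # (1,2,3) vs (4,5,6): pooled sd 1, SE sqrt(2/3), t = 3.674, df 4
        cohort = make_cohort({("roi_00", "roi_01"): [1, 2, 3, 4, 5, 6]},
                             ["SI"] * 3 + ["noSI"] * 3, generic_labels(4))
        stats = cs.edgewise_t(cohort, "SI", "noSI")
        assert stats.df == 4
        assert stats.t_values[0, 1] == pytest.approx(
            3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_90_region_cohort_has_4005_statistics(self):
        rng = np.random.default_rng(0)
        spec = cs.CohortSpec(n_group_a=3, n_group_b=3, n_controls=0, seed=1)
        cohort = cs.generate_edge_cohort(spec)
        stats = cs.edgewise_t(cohort, "SI", "noSI")
        assert stats.condensed().size == 4005

    def test_subject_order_within_groups_irrelevant(self, rng):
        spec = cs.CohortSpec(n_group_a=5, n_group_b=5, n_controls=0,
                             n_regions=6, seed=2)
        cohort = cs.generate_edge_cohort(spec)
        t1 = cs.edgewise_t(cohort, "SI", "noSI").t_values
        # shuffle subjects (networks + manifest rows) coherently
        perm = rng.permutation(cohort.n_subjects)
        shuffled = cs.CohortDataset(
            cohort.manifest.iloc[perm],
            networks=[cohort.networks[i] for i in perm])
        t2 = cs.edgewise_t(shuffled, "SI", "noSI").t_values
        assert np.allclose(t1, t2, atol=1e-12)

    def test_unknown_group_rejected(self):
        cohort = make_cohort({("roi_00", "roi_01"): [1, 2, 3, 4]},
                             ["SI"] * 2 + ["noSI"] * 2, generic_labels(4))
        with pytest.raises(KeyError):
            cs.edgewise_t(cohort, "SI", "bogus")


class TestComponents:
    LABELS = ("A", "B", "C", "D", "E", "F")
    EDGES = {("A", "B"): 5.0, ("B", "C"): 4.5, ("D", "E"): 4.3,
             ("E", "F"): 1.0}

    def test_threshold_above_max_gives_empty(self):
        comps = suprathreshold_components(
            stat_map(self.EDGES, self.LABELS), 10.0)
        assert comps == []

    def test_example_components_match_oracle(self):
        comps = suprathreshold_components(
            stat_map(self.EDGES, self.LABELS), 4.2)
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].edges == frozenset({("A", "B"), ("B", "C")})
        assert comps[1].edges == frozenset({("D", "E")})
        oracle = components_by_networkx(self.EDGES, 4.2)
        assert [c.edges for c in comps] == [o[0] for o in oracle]
        assert [c.nodes for c in comps] == [o[1] for o in oracle]

    def test_random_maps_match_oracle(self, rng):
        labels = generic_labels(12)
        for _ in range(20):
            iu, ju = np.triu_indices(12, k=1)
            t = rng.normal(scale=3.0, size=iu.size)
            edges = {(labels[i], labels[j]): v
                     for i, j, v in zip(iu, ju, t)}
            comps = suprathreshold_components(stat_map(edges, labels), 2.0)
            oracle = components_by_networkx(edges, 2.0)
            assert [c.edges for c in comps] == [o[0] for o in oracle]

    def test_strict_inequality_at_threshold(self):
        comps = suprathreshold_components(
            stat_map({("A", "B"): 4.2}, self.LABELS), 4.2)
        assert comps == []

    def test_monotone_in_threshold(self, rng):
        labels = generic_labels(10)
        iu, ju = np.triu_indices(10, k=1)
        t = rng.normal(scale=3.0, size=iu.size)
        edges = {(labels[i], labels[j]): v for i, j, v in zip(iu, ju, t)}
        sizes = []
        for thr in (1.0, 2.0, 3.0, 4.0):
            comps = suprathreshold_components(stat_map(edges, labels), thr)
            sizes.append(max((c.size for c in comps), default=0))
        assert sizes == sorted(sizes, reverse=True)


class TestHubs:
    def test_single_edge_has_no_hubs(self):
        comp = cs.Component.from_edges([("A", "B")])
        assert hub_detect(comp) == set()

    def test_star_center_is_only_hub(self):
        comp = cs.Component.from_edges(
            [("hub", leaf) for leaf in "ABCDE"])
        assert hub_detect(comp) == {"hub"}

    def test_parcellation_scope_flags_fronto_thalamic_hubs(self):
        comp = cs.Component.from_edges(
            [e.edge for e in cs.fronto_thalamic_subnetwork()])
        hubs = hub_detect(comp, n_total_nodes=90)
        assert hubs == {"Frontal_Sup_Orb_L", "Thalamus_L", "Thalamus_R"}

    def test_component_scope_differs_from_parcellation_scope(self):
        comp = cs.Component.from_edges(
            [e.edge for e in cs.fronto_thalamic_subnetwork()])
        assert hub_detect(comp) == {"Frontal_Sup_Orb_L"}


class TestPermutationTest:
    def _planted_cohort(self, seed=0):
        spec = cs.CohortSpec(
            n_group_a=12, n_group_b=12, n_controls=0, n_regions=10,
            background_sd=0.0, edge_sd=0.1, seed=seed,
            planted=(cs.PlantedEffect(("roi_00", "roi_01"), 0.10, 0.45),
                     cs.PlantedEffect(("roi_01", "roi_02"), 0.15, 0.50)),
        )
        return cs.generate_edge_cohort(spec)

    def test_planted_component_is_significant_and_deterministic(self):
        cohort = self._planted_cohort()
        res1 = cs.nbs_test(cohort, "SI", "noSI", threshold=4.2,
                           n_perm=500, seed=7)
        res2 = cs.nbs_test(cohort, "SI", "noSI", threshold=4.2,
                           n_perm=500, seed=7)
        assert res1.significant_components
        top = res1.significant_components[0]
        assert top.edges == frozenset({("roi_00", "roi_01"),
                                       ("roi_01", "roi_02")})
        assert np.array_equal(res1.null_max_sizes, res2.null_max_sizes)
        assert [c.pvalue for c in res1.components] == [
            c.pvalue for c in res2.components]

    def test_observed_labelling_counts_in_null(self):
        cohort = self._planted_cohort()
        res = cs.nbs_test(cohort, "SI", "noSI", threshold=4.2,
                          n_perm=500, seed=1)
        assert res.null_max_sizes.size == 500
        assert res.null_max_sizes[0] == res.components[0].size
        assert min(c.pvalue for c in res.components) >= 1.0 / 500

    def test_exact_permutation_matches_enumeration_oracle(self):
        spec = cs.CohortSpec(
            n_group_a=3, n_group_b=3, n_controls=0, n_regions=5,
            background_sd=0.0, edge_sd=0.15, seed=12,
            planted=(cs.PlantedEffect(("roi_00", "roi_01"), 0.1, 0.8),),
        )
        cohort = cs.generate_edge_cohort(spec)
        res = cs.nbs_test(cohort, "SI", "noSI", threshold=2.5, exact=True,
                          n_perm=100)
        assert res.n_perm == 20  # C(6, 3) label splits
        p_oracle = exact_nbs_pvalue(
            cohort.edge_matrix(), cohort.group_mask("noSI"),
            cohort.edge_pairs(), threshold=2.5)
        assert res.components[0].pvalue == pytest.approx(p_oracle, abs=1e-12)

    def test_two_sided_tail_detects_reversed_effect(self):
        spec = cs.CohortSpec(
            n_group_a=12, n_group_b=12, n_controls=0, n_regions=8,
            background_sd=0.0, edge_sd=0.1, seed=3,
            planted=(cs.PlantedEffect(("roi_00", "roi_01"), 0.6, 0.1),),
        )
        cohort = cs.generate_edge_cohort(spec)
        one_sided = cs.nbs_test(cohort, "SI", "noSI", threshold=4.2,
                                n_perm=200, seed=0)
        two_sided = cs.nbs_test(cohort, "SI", "noSI", threshold=4.2,
                                n_perm=200, seed=0, tail="two_sided")
        assert not one_sided.components  # effect is in the other direction
        assert two_sided.significant_components

    def test_small_n_perm_rejected(self):
        cohort = self._planted_cohort()
        with pytest.raises(ValueError):
            cs.nbs_test(cohort, "SI", "noSI", n_perm=50)

    def test_summary_and_edge_table(self):
        cohort = self._planted_cohort()
        res = cs.nbs_test(cohort, "SI", "noSI", threshold=4.2,
                          n_perm=200, seed=5)
        table = res.edge_table()
        assert list(table.columns) == ["region_i", "region_j", "t",
                                       "mean_a", "mean_b"]
        assert len(table) == res.components[0].size
        text = res.summary()
        assert "Network-based statistics" in text
        assert "noSI_minus_SI" in text
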