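"""Species-role metrics, scaling, rankings, preferences, and contrasts."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pollinet import (
    BipartiteNetwork,
    UndefinedMetricError,
    centrality,
    family_preference,
    feature_scale,
    functional_complementarity,
    loglog_attraction_slope,
    native_contrast,
    node_longevity,
    one_mode_projection,
    species_role_table,
    top_k_union,
    visitation_rate,
)
from conftest import make_record
import oracles


def web(weights, plants=None, visitors=None):
    return BipartiteNetwork.from_weights(weights, plants, visitors, prune=False)


class TestOneModeProjection:
    def test_exclusive_partners_give_isolated_nodes(self):
        g = one_mode_projection(web(np.diag([2, 2])), "plants")
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 2

    def test_shared_visitor_links_plants(self):
        g = one_mode_projection(web([[1, 1], [1, 0]]), "plants")
        assert g.number_of_edges() == 1

    def test_universal_visitor_makes_triangle(self):
        g = one_mode_projection(web([[1], [1], [1]]), "plants")
        assert g.number_of_edges() == 3  # K3

    def test_no_self_loops(self):
        g = one_mode_projection(web([[2, 1], [1, 1]]), "visitors")
        assert all(u != v for u, v in g.edges)


class TestCentrality:
    def test_path_graph_hand_values(self):
        g = nx.path_graph(["a", "b", "c"])
        cent = centrality(g)
        assert cent["betweenness"]["b"] == 1.0
        assert cent["betweenness"]["a"] == 0.0
        assert cent["closeness"]["b"] == 1.0
        assert cent["closeness"]["a"] == pytest.approx(2 / 3)

    def test_complete_graph_symmetry(self):
        cent = centrality(nx.complete_graph(4))
        assert all(v == 0 for v in cent["betweenness"].values())
        assert all(v == 1.0 for v in cent["closeness"].values())

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b")
        assert centrality(g)["closeness"]["c"] == 0.0

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            nodes = list(range(n))
            edges = [e for e in itertools.combinations(nodes, 2) if rng.random() < 0.4]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            cent = centrality(g)
            bc = oracles.betweenness_bruteforce(nodes, edges)
            cc = oracles.closeness_bruteforce(nodes, edges)
            for node in nodes:
                assert cent["betweenness"][node] == pytest.approx(bc[node])
                assert cent["closeness"][node] == pytest.approx(cc[node])


class TestNodeLongevity:
    def test_single_week_is_one(self):
        assert node_longevity([make_record(week=25)])["Trifolium repens"] == 1

    def test_span_is_inclusive(self):
        recs = [make_record(week=20), make_record(week=23)]
        assert node_longevity(recs)["Trifolium repens"] == 4

    def test_pools_years_by_week(self):
        import datetime as dt

        r1 = make_record(week=20)
        r2 = make_record(week=22)
        object.__setattr__(r2, "date", dt.date.fromisocalendar(2018, 22, 3))
        assert node_longevity([r1, r2])["Trifolium repens"] == 3

    def test_zero_visit_records_do_not_count_as_activity(self):
        recs = [make_record(week=20, visits=0), make_record(week=25)]
        assert node_longevity(recs)["Trifolium repens"] == 1


class TestVisitationRate:
    def test_visits_per_display_unit(self):
        recs = [make_record(visits=10, units=2, size=5.0)]
        assert visitation_rate(recs)["Trifolium repens"] == pytest.approx(1.0)

    def test_single_flower_inflation(self):
        recs = [make_record(visits=1, units=1, size=150.0)]
        assert visitation_rate(recs)["Trifolium repens"] == pytest.approx(1 / 150.0)

    def test_scale_invariance(self):
        r1 = [make_record(visits=5, units=10, size=2.0)]
        r2 = [make_record(visits=10, units=20, size=2.0)]
        assert visitation_rate(r1)["Trifolium repens"] == pytest.approx(
            visitation_rate(r2)["Trifolium repens"]
        )

    def test_unknown_display_flagged_none(self):
        recs = [make_record(size=None)]
        assert visitation_rate(recs)["Trifolium repens"] is None


class TestFunctionalComplementarity:
    def test_identical_rows_zero(self):
        fc, contrib = functional_complementarity(web([[2, 0], [2, 0]]))
        assert fc == 0.0

    def test_two_species_closed_form(self):
        fc, contrib = functional_complementarity(web([[2, 0], [0, 2]]))
        assert fc == pytest.approx(2 * np.sqrt(2))

    def test_duplicate_species_contributes_nothing(self):
        base = np.array([[3, 0, 1], [0, 2, 2], [1, 1, 0]])
        dup = np.vstack([base, base[0]])
        fc_dup, contrib = functional_complementarity(
            web(dup, plants=["a", "b", "c", "a2"])
        )
        assert contrib["a2"] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_when_novel_species_added(self):
        base = np.array([[3, 0, 0], [0, 3, 0]])
        fc_base, _ = functional_complementarity(web(base))
        grown = np.vstack([base, [0, 0, 5]])
        fc_grown, _ = functional_complementarity(web(grown))
        assert fc_grown >= fc_base

    def test_permutation_invariant(self, rng):
        w = rng.poisson(2, (5, 4)) + 1
        fc1, _ = functional_complementarity(web(w))
        fc2, _ = functional_complementarity(web(w[rng.permutation(5)]))
        assert fc1 == pytest.approx(fc2)

    def test_single_species_undefined(self):
        with pytest.raises(UndefinedMetricError):
            functional_complementarity(web([[1, 2]]))


class TestFeatureScale:
    def test_linear_map(self):
        assert feature_scale([2, 4, 6]).tolist() == [0.0, 0.5, 1.0]

    def test_constant_vector_maps_to_zero(self):
        assert feature_scale([5.0]).tolist() == [0.0]
        assert feature_scale([3, 3, 3]).tolist() == [0.0, 0.0, 0.0]

    def test_bounded_and_attains_extremes(self, rng):
        x = rng.normal(size=50)
        s = feature_scale(x)
        assert s.min() == 0.0 and s.max() == 1.0
        assert ((s >= 0) & (s <= 1)).all()

    def test_nan_preserved(self):
        s = feature_scale([1.0, np.nan, 3.0])
        assert np.isnan(s[1]) and s[0] == 0.0 and s[2] == 1.0


class TestRoleTableAndRanking:
    def test_table_covers_all_species_with_scaled_columns(self, synthetic_records):
        table = species_role_table(synthetic_records, guild="plants")
        net_plants = {r.plant_taxon for r in synthetic_records if r.visits > 0}
        assert set(table.index) == net_plants
        for col in ("weighted_degree", "longevity", "fc"):
            scaled = table["scaled_" + col].dropna()
            if scaled.nunique() > 1:
                assert scaled.min() == 0.0 and scaled.max() == 1.0

    def test_small_n_everything_ranked(self):
        table = pd.DataFrame(
            {"weighted_degree": [3.0, 1.0, 2.0]}, index=["a", "b", "c"]
        )
        top = top_k_union(table, k=10, metrics=("weighted_degree",))
        assert sorted(top.index) == ["a", "b", "c"]

    def test_disjoint_top_lists_union(self):
        table = pd.DataFrame(
            {
                "m1": [10, 9, 1, 1],
                "m2": [1, 1, 10, 9],
            },
            index=["a", "b", "c", "d"],
        )
        top = top_k_union(table, k=2, metrics=("m1", "m2"))
        assert sorted(top.index) == ["a", "b", "c", "d"]
        assert top.loc["a", "m1"] and not top.loc["a", "m2"]

    def test_ties_break_alphabetically(self):
        table = pd.DataFrame({"m": [1.0, 1.0, 1.0]}, index=["c", "a", "b"])
        top = top_k_union(table, k=2, metrics=("m",))
        assert sorted(top.index) == ["a", "b"]

    def test_planted_generalists_dominate_rankings(self, synthetic_records):
        table = species_role_table(synthetic_records, guild="plants")
        top = top_k_union(table, k=10)
        # the most-visited species should appear in several metric top-10s
        best = table["weighted_degree"].idxmax()
        assert top.loc[best, "n_metrics"] >= 3


class TestFamilyPreference:
    def test_single_family_closure(self):
        recs = [make_record()]
        table = species_role_table(recs, guild="plants")
        prefs = family_preference(table, recs, k=10)
        assert prefs == {"Fabaceae": pytest.approx(0.0)}

    def test_absent_family_gets_minus_background_share(self):
        # two families; only one reaches the single-metric top-1 list
        recs = [
            make_record(plant="Planta a", family="Asteraceae", visits=10, units=10, size=3.0),
            make_record(plant="Plantb b", family="Fabaceae", visits=1, units=10, size=7.0),
        ]
        table = species_role_table(recs, guild="plants")
        prefs = family_preference(table, recs, k=1, metrics=("weighted_degree",))
        assert prefs["Fabaceae"] == pytest.approx(-0.7)
        assert prefs["Asteraceae"] == pytest.approx(0.7)

    def test_preferences_sum_to_zero(self, synthetic_records):
        table = species_role_table(synthetic_records, guild="plants")
        prefs = family_preference(table, synthetic_records)
        assert sum(prefs.values()) == pytest.approx(0.0, abs=1e-9)


class TestNativeContrast:
    def test_identical_groups_not_significant(self, rng):
        n = 20
        table = pd.DataFrame(
            {
                # both status groups hold five 5s and five 7s
                "weighted_degree": np.tile([5.0, 7.0], n // 2),
                "plant_native": ["native"] * (n // 2) + ["non-native"] * (n // 2),
            },
            index=[f"s{i}" for i in range(n)],
        )
        res = native_contrast(table, metrics=("weighted_degree",), n_perm=2000, seed=0)
        row = res.loc["weighted_degree"]
        assert row["difference"] == pytest.approx(0.0)
        assert row["p_value"] > 0.9

    def test_bonferroni_threshold_is_007(self):
        assert round(0.05 / 7, 3) == 0.007

    def test_planted_deficit_recovered(self, rng):
        nat = rng.normal(10, 1, 50)
        non = rng.normal(6, 1, 50)
        table = pd.DataFrame(
            {
                "weighted_degree": np.concatenate([nat, non]),
                "plant_native": ["native"] * 50 + ["non-native"] * 50,
            },
            index=[f"s{i}" for i in range(100)],
        )
        res = native_contrast(table, metrics=("weighted_degree",), n_perm=3000, seed=1)
        row = res.loc["weighted_degree"]
        assert row["difference"] < 0 and bool(row["significant"])

    def test_empty_group_undefined(self):
        table = pd.DataFrame(
            {"weighted_degree": [1.0], "plant_native": ["native"]}, index=["a"]
        )
        with pytest.raises(UndefinedMetricError):
            native_contrast(table, metrics=("weighted_degree",))


class TestLogLogSlope:
    def test_proportional_visits_give_unit_slope(self):
        recs = [
            make_record(plant=f"Planta p{i}", visits=int(d), units=int(d), size=1.0)
            for i, d in enumerate([1000, 3000, 10000, 30000, 100000])
        ]
        fit = loglog_attraction_slope(recs)
        assert fit.slope == pytest.approx(1.0, abs=0.01)

    def test_constant_visits_give_zero_slope(self):
        recs = [
            make_record(plant=f"Planta p{i}", visits=50, units=u, size=2.0)
            for i, u in enumerate([10, 100, 1000, 10000])
        ]
        fit = loglog_attraction_slope(recs)
        assert fit.slope == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_display_undefined(self):
        recs = [
            make_record(plant=f"Planta p{i}", visits=i + 1, units=10, size=2.0)
            for i in range(4)
        ]
        with pytest.raises(UndefinedMetricError):
            loglog_attraction_slope(recs)
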