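import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fosnet.network as net
from fosnet.io import FosCountTable

import oracles
from conftest import REGIONS, correlation_result_from_r, make_fos_frame


class TestFisherTransform:
    def test_zero_is_a_fixed_point(self):
        assert net.fisher_z(0.0) == 0.0
        assert net.inverse_fisher(0.0) == 0.0

    def test_half_maps_to_half_log_three(self):
        assert net.fisher_z(0.5) == pytest.approx(0.5 * math.log(3.0), abs=1e-12)
        assert net.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    @pytest.mark.parametrize("r", np.round(np.arange(-0.99, 1.0, 0.11), 2).tolist())
    def test_roundtrip_identity(self, r):
        assert net.inverse_fisher(net.fisher_z(r)) == pytest.approx(r, abs=1e-12)

    @given(st.floats(-0.999, 0.999))
    def test_odd_function(self, r):
        assert net.fisher_z(-r) == pytest.approx(-net.fisher_z(r), abs=1e-12)

    def test_clamping_contains_degenerate_correlations(self):
        assert math.isfinite(net.fisher_z(1.0))
        with pytest.raises(ValueError):
            net.fisher_z(1.0, clamp=False)


class TestRToT:
    def test_zero_correlation_gives_zero_t(self):
        t, df = net.r_to_t(0.0, 20)
        assert t == 0.0 and df == 18

    def test_hand_computed_values(self):
        t, df = net.r_to_t(0.5, 11)
        assert df == 9
        assert t == pytest.approx(0.5 * 3 / math.sqrt(0.75), abs=1e-12)
        assert t == pytest.approx(1.7321, abs=1e-4)
        t, df = net.r_to_t(0.9, 12)
        assert df == 10
        assert t == pytest.approx(0.9 * math.sqrt(10) / math.sqrt(0.19), abs=1e-12)
        assert t == pytest.approx(6.5293, abs=1e-4)

    def test_perfect_correlation_signals_infinite_t(self):
        t, df = net.r_to_t(1.0, 5)
        assert math.isinf(t) and t > 0


class TestPearson:
    def test_perfect_linear_relationships(self):
        r, p, n = net.pearson_r_p([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0) and n == 3
        r, _, _ = net.pearson_r_p([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_five_point_case(self):
        r, p, n = net.pearson_r_p([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r == pytest.approx(0.8, abs=1e-12)  # covariance 8 / sqrt(10*10)
        assert p == pytest.approx(oracles.t_two_tailed_p(2.3094, 3), abs=1e-4)
        assert p == pytest.approx(0.1041, abs=1e-4)

    def test_constant_vector_is_flagged_missing(self):
        with pytest.warns(UserWarning):
            r, p, n = net.pearson_r_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p) and n == 4

    def test_pairwise_deletion_of_missing_values(self):
        x = [1.0, 2.0, math.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, math.nan]
        r, p, n = net.pearson_r_p(x, y)
        assert n == 3 and r == pytest.approx(1.0)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_loop_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r, p, n = net.pearson_r_p(x, y)
        r0, p0, n0 = oracles.pearson_p_loop(list(x), list(y))
        assert n == n0 and r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-10)


class TestConditionCorrelationMatrix:
    def test_two_region_perfect_correlation(self):
        arr = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        frame = make_fos_frame({"COT": arr}, regions=["CeA", "VTA"])
        cr = net.condition_correlation_matrix(FosCountTable(frame), "COT")
        assert cr.r.at["CeA", "VTA"] == pytest.approx(1.0)
        assert cr.n.at["CeA", "VTA"] == 4

    def test_constant_region_marks_only_its_pairs_missing(self, rng):
        arr = rng.normal(100, 20, (6, 3))
        arr[:, 1] = 50.0
        regions = ["CeA", "PVN", "VTA"]
        with pytest.warns(net.ConstantRegionWarning):
            cr = net.correlation_matrix_from_array(arr, regions)
        assert cr.missing.at["CeA", "PVN"] and cr.missing.at["PVN", "VTA"]
        assert not cr.missing.at["CeA", "VTA"]

    def test_matches_brute_force_on_full_synthetic_table(self, rng):
        arr = rng.normal(100, 25, (9, 11))
        cr = net.condition_correlation_matrix(
            FosCountTable(make_fos_frame({"BLT": arr})), "BLT"
        )
        expected = oracles.all_pairs(arr.tolist())
        for (i, j), (r0, p0, n0) in expected.items():
            a, b = REGIONS[i], REGIONS[j]
            assert cr.r.at[a, b] == pytest.approx(r0, abs=1e-10)
            assert cr.p.at[a, b] == pytest.approx(p0, abs=1e-10)
            assert cr.n.at[a, b] == n0

    def test_sex_stratification_uses_only_that_sex(self, rng):
        arr = rng.normal(100, 25, (8, 11))
        table = FosCountTable(make_fos_frame({"BOT": arr}))
        pooled = net.condition_correlation_matrix(table, "BOT")
        females = net.condition_correlation_matrix(table, "BOT", pool_sexes=False, sex="F")
        assert pooled.n.at["CeA", "VTA"] == 8
        assert females.n.at["CeA", "VTA"] == 4


class TestThresholdNetwork:
    def test_nothing_significant_means_all_isolates(self, rng):
        cr = net.correlation_matrix_from_array(rng.standard_normal((12, 11)), REGIONS)
        g = net.threshold_network(cr, alpha=1e-12)
        assert g.edges == ()
        assert len(g.isolates) == 11
        assert g.components == ()

    def test_single_significant_pair(self):
        cr = correlation_result_from_r({("CeA", "VTA"): 0.95}, n=10, regions=list(REGIONS))
        g = net.threshold_network(cr, alpha=0.05)
        assert [(e.region_a, e.region_b, e.sign) for e in g.edges] == [("CeA", "VTA", "+")]
        assert g.components == (frozenset({"CeA", "VTA"}),)
        assert len(g.isolates) == 9

    def test_three_node_chain_forms_one_component(self):
        cr = correlation_result_from_r(
            {("vmPFC", "aIC"): 0.95, ("aIC", "NAcC"): -0.95},
            n=10,
            regions=list(REGIONS),
        )
        g = net.threshold_network(cr)
        comps = oracles.connected_components(
            REGIONS, [(e.region_a, e.region_b) for e in g.edges]
        )
        assert g.components == tuple(comps)
        assert sorted(
            net.network_summary(g).degrees[r] for r in ("vmPFC", "aIC", "NAcC")
        ) == [1, 1, 2]
        signs = {(e.region_a, e.region_b): e.sign for e in g.edges}
        assert signs[("aIC", "NAcC")] == "-"

    def test_adjacency_zeroes_non_significant_pairs(self):
        cr = correlation_result_from_r({("CeA", "VTA"): 0.95, ("SON", "PVN"): 0.1},
                                       n=10, regions=list(REGIONS))
        adj = net.threshold_network(cr).adjacency()
        assert adj.at["CeA", "VTA"] == pytest.approx(0.95)
        assert adj.at["SON", "PVN"] == 0.0
        assert np.allclose(adj.to_numpy(), adj.to_numpy().T)


class TestDifferentialNetwork:
    def test_subtracting_a_matrix_from_itself_retains_nothing(self, rng):
        cr = net.correlation_matrix_from_array(rng.normal(size=(10, 11)), REGIONS)
        diff = net.differential_network(cr, cr)
        assert diff.edges == ()
        assert (diff.table["z_diff"] == 0).all()
        assert (diff.table["t"] == 0).all()

    def test_strong_task_only_pair_is_retained(self):
        regions = list(REGIONS)
        task = correlation_result_from_r({("CeA", "VTA"): 0.9}, n=12, regions=regions)
        control = correlation_result_from_r({}, n=12, regions=regions)
        diff = net.differential_network(task, control, n_rule="task_n")
        row = diff.table.set_index(["region_a", "region_b"]).loc[("CeA", "VTA")]
        assert row["z_diff"] == pytest.approx(1.4722, abs=1e-4)
        assert row["r_diff"] == pytest.approx(0.9, abs=1e-12)
        assert row["t"] == pytest.approx(6.5293, abs=1e-4)
        assert row["df"] == 10
        assert row["p"] < 0.001
        assert {(e.region_a, e.region_b) for e in diff.edges} == {("CeA", "VTA")}

    def test_small_difference_is_not_retained(self):
        regions = list(REGIONS)
        task = correlation_result_from_r({("CeA", "VTA"): 0.3}, n=8, regions=regions)
        control = correlation_result_from_r({("CeA", "VTA"): 0.25}, n=8, regions=regions)
        diff = net.differential_network(task, control)
        row = diff.table.set_index(["region_a", "region_b"]).loc[("CeA", "VTA")]
        assert row["r_diff"] == pytest.approx(0.055, abs=5e-3)
        assert row["t"] == pytest.approx(0.135, abs=5e-3)
        assert abs(row["t"]) < oracles.t_critical(6, 0.05)
        assert diff.edges == ()

    def test_n_rule_selects_the_n_for_the_retest(self):
        regions = list(REGIONS)
        task = correlation_result_from_r({("CeA", "VTA"): 0.6}, n=20, regions=regions)
        control = correlation_result_from_r({}, n=5, regions=regions)
        for rule, expected in (("task_n", 20), ("control_n", 5), ("min_n", 5)):
            diff = net.differential_network(task, control, n_rule=rule)
            assert (diff.table["n_used"] == expected).all(), rule

    def test_mismatched_region_sets_are_rejected(self, rng):
        cr1 = net.correlation_matrix_from_array(rng.normal(size=(8, 3)), ("A", "B", "C"))
        cr2 = net.correlation_matrix_from_array(rng.normal(size=(8, 3)), ("A", "B", "D"))
        with pytest.raises(ValueError):
            net.differential_network(cr1, cr2)

    def test_missing_pairs_are_excluded_and_reported(self, rng):
        arr = rng.normal(100, 10, (8, 3))
        arr[:, 0] = 42.0  # constant region in the task condition
        regions = ("CeA", "PVN", "VTA")
        with pytest.warns(net.ConstantRegionWarning):
            task = net.correlation_matrix_from_array(arr, regions)
        control = net.correlation_matrix_from_array(rng.normal(size=(8, 3)), regions)
        diff = net.differential_network(task, control)
        assert set(diff.excluded_pairs) == {("CeA", "PVN"), ("CeA", "VTA")}
        assert len(diff.table) == 1

    def test_retention_is_monotone_in_zdiff_magnitude(self):
        regions = list(REGIONS)
        control = correlation_result_from_r({}, n=12, regions=regions)
        retained = []
        for r in (0.1, 0.3, 0.5, 0.7, 0.9):
            task = correlation_result_from_r({("CeA", "VTA"): r}, n=12, regions=regions)
            diff = net.differential_network(task, control)
            retained.append(len(diff.edges))
        assert retained == sorted(retained)
        assert retained[0] == 0 and retained[-1] == 1

    def test_subtract_thresholded_zeroes_nonsignificant_inputs_first(self):
        regions = list(REGIONS)
        # r = 0.5 at n = 12 is not significant (p ~ 0.098), so the
        # thresholded reading zeroes it and the same pair differs.
        task = correlation_result_from_r({("CeA", "VTA"): 0.5}, n=12, regions=regions)
        control = correlation_result_from_r({("CeA", "VTA"): 0.5}, n=12, regions=regions)
        raw = net.differential_network(task, control)
        thr = net.differential_network(task, control, subtract_thresholded=True)
        pair = ("CeA", "VTA")
        raw_row = raw.table.set_index(["region_a", "region_b"]).loc[pair]
        thr_row = thr.table.set_index(["region_a", "region_b"]).loc[pair]
        assert raw_row["z_diff"] == 0.0
        assert thr_row["z_diff"] == 0.0  # both zeroed -> identical
        assert (thr.table["r_task"] == 0).all()


class TestPermutationInvariance:
    def test_region_relabeling_permutes_outputs_identically(self, rng):
        arr = rng.normal(100, 20, (10, 5))
        regions = ["vmPFC", "aIC", "NAcC", "CeA", "VTA"]
        perm = [3, 0, 4, 1, 2]
        cr = net.correlation_matrix_from_array(arr, regions)
        cr_p = net.correlation_matrix_from_array(arr[:, perm], [regions[i] for i in perm])
        for a in regions:
            for b in regions:
                if a != b:
                    assert cr.r.at[a, b] == pytest.approx(cr_p.r.at[a, b], abs=1e-12)
        g = net.threshold_network(cr)
        g_p = net.threshold_network(cr_p)
        edges = {frozenset((e.region_a, e.region_b)) for e in g.edges}
        edges_p = {frozenset((e.region_a, e.region_b)) for e in g_p.edges}
        assert edges == edges_p


class TestNetworkSummary:
    def test_empty_network_has_all_zero_degrees(self, rng):
        cr = net.correlation_matrix_from_array(rng.standard_normal((12, 11)), REGIONS)
        s = net.network_summary(net.threshold_network(cr, alpha=1e-12))
        assert set(s.degrees.values()) == {0}
        assert s.hub is None
        assert not s.all_regions_involved

    def test_star_graph_ranks_the_hub_first(self):
        regions = list(REGIONS)
        cr = correlation_result_from_r(
            {("VTA", spoke): 0.95 for spoke in ("vmPFC", "aIC", "NAcC", "CeA")},
            n=10,
            regions=regions,
        )
        s = net.network_summary(net.threshold_network(cr))
        assert s.degrees["VTA"] == 4
        assert s.ranked[0] == "VTA"
        assert all(s.degrees[x] == 1 for x in ("vmPFC", "aIC", "NAcC", "CeA"))

    def test_degree_sum_is_twice_edge_count(self, rng):
        for _ in range(5):
            cr = net.correlation_matrix_from_array(rng.normal(size=(8, 11)), REGIONS)
            g = net.threshold_network(cr, alpha=0.3)
            s = net.network_summary(g)
            assert sum(s.degrees.values()) == 2 * s.n_edges

    def test_ties_break_by_registry_order(self):
        cr = correlation_result_from_r(
            {("aIC", "NAcC"): 0.95, ("CeA", "VTA"): 0.95}, n=10, regions=list(REGIONS)
        )
        s = net.network_summary(net.threshold_network(cr))
        assert s.ranked[:4] == ("aIC", "NAcC", "CeA", "VTA")

    def test_betweenness_is_available_on_request(self):
        cr = correlation_result_from_r(
            {("vmPFC", "aIC"): 0.95, ("aIC", "NAcC"): 0.95}, n=10, regions=list(REGIONS)
        )
        s = net.network_summary(net.threshold_network(cr), betweenness=True)
        assert s.betweenness["aIC"] > s.betweenness["vmPFC"]


class TestModelObjects:
    def test_fit_matches_functional_path_and_renders_summary(self, rng):
        arr = rng.normal(100, 20, (10, 11))
        table = FosCountTable(make_fos_frame({"BLT": arr, "COT": rng.normal(100, 20, (10, 11))}))
        res = net.CoactivationNetwork(table, "BLT").fit(alpha=0.05)
        direct = net.threshold_network(
            net.condition_correlation_matrix(table, "BLT"), alpha=0.05
        )
        assert {(e.region_a, e.region_b) for e in res.network.edges} == {
            (e.region_a, e.region_b) for e in direct.edges
        }
        text = res.summary()
        assert "Coactivation network" in text and "alpha" in text

        dres = net.DifferentialCoactivationNetwork(table, "BLT", "COT").fit()
        assert "BLT - COT" in dres.summary()
        assert len(dres.table) == 55

    def test_from_dataframe_constructor(self, rng):
        frame = make_fos_frame({"BOT": rng.normal(100, 20, (8, 11))})
        res = net.CoactivationNetwork.from_dataframe(frame, "BOT").fit()
        assert res.alpha == 0.05

    def test_plot_draws_signed_edges(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        frame = make_fos_frame({"BOT": rng.normal(100, 20, (8, 11))})
        res = net.CoactivationNetwork.from_dataframe(frame, "BOT").fit(alpha=0.5)
        ax = res.plot()
        assert ax.get_title() == "BOT"
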