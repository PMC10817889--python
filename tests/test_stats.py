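import numpy as np
import pandas as pd
import pytest

from spanmerge import (
    AccuracyRecord,
    CategoricalGrid,
    MergedCodeScheme,
    jenks_breaks,
    merge,
    mismatch_stats,
    span_accuracy,
    unresolved_stats,
    verify_output,
    weighted_accuracy,
)
from spanmerge.stats import jenks_assign, jenks_objective
from spanmerge.taxonomy import AttributeRow

from .conftest import NATURAL, NATURAL_CDL, make_grid
from .oracles import oracle_jenks_cost, partition_cost


class TestMismatchStats:
    def test_twenty_percent_vineyard_conflict(self, table):
        # one zone, 10 vineyard pixels, 2 of them conflicting
        nvc = np.full((2, 5), 7961, dtype=np.int32)
        cdl = np.full((2, 5), 69, dtype=np.int32)
        cdl[0, 0] = cdl[0, 1] = NATURAL_CDL
        zones = np.full((2, 5), 42, dtype=np.int32)
        out = mismatch_stats(make_grid(nvc), make_grid(cdl), make_grid(zones),
                             table, year=2017)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["NVC_Name"] == "Vineyard"
        assert row["CDL_Class"] == NATURAL_CDL
        assert row["NCells_Mismatch"] == 2
        assert row["NCells_NVCClass_perCounty"] == 10
        assert row["Pct_Mismatch"] == pytest.approx(20.0)
        assert row["NVC_CDL_Pair"] == "Vineyard - Shrubland"

    def test_zone_without_agriculture_emits_no_records(self, table):
        nvc = make_grid(np.full((4, 4), NATURAL))
        cdl = make_grid(np.full((4, 4), 1))
        zones = make_grid(np.full((4, 4), 7))
        out = mismatch_stats(nvc, cdl, zones, table, year=2017)
        assert out.empty
        assert list(out.columns)[:3] == ["FIPS", "State", "CDL_Year"]

    def test_variant_codes_pool_to_one_group_row(self, table):
        # two vineyard variants conflicting in one zone aggregate under one name
        nvc = np.array([[7961, 7971, 7981, 7991]], dtype=np.int32)
        cdl = np.full((1, 4), NATURAL_CDL, dtype=np.int32)
        zones = np.full((1, 4), 1, dtype=np.int32)
        out = mismatch_stats(make_grid(nvc), make_grid(cdl), make_grid(zones),
                             table, year=2017)
        assert len(out) == 1
        assert out.iloc[0]["NCells_Mismatch"] == 4
        assert out.iloc[0]["NCells_NVCClass_perCounty"] == 4

    def test_sum_over_pairs_equals_total_step1_mismatch(self, table):
        from spanmerge import FixtureSpec, generate_pair, merge_step1

        pair = generate_pair(FixtureSpec(rows=64, cols=64, seed=4, n_zones=3), table)
        cdl = pair.cdl_by_year[2016]
        out = mismatch_stats(pair.nvc, cdl, pair.zones, table, year=2016)
        step1 = merge_step1(pair.nvc, cdl, table)
        assert out["NCells_Mismatch"].sum() == step1.counts["mismatched"]
        assert ((out["Pct_Mismatch"] >= 0) & (out["Pct_Mismatch"] <= 100)).all()


class TestUnresolvedStats:
    def _merge_fixture(self, table, with_conflict):
        nvc = np.full((10, 10), 7964, dtype=np.int32)
        cdl = np.full((10, 10), 1, dtype=np.int32)
        if with_conflict:
            nvc[0:2, 0:2] = NATURAL
            nvc[5, 5] = 7961  # resolvable: matched corn everywhere around
        return merge(make_grid(nvc), make_grid(cdl), table)

    def test_fully_resolvable_conflicts_give_zero_rows_everywhere(self, table):
        res = self._merge_fixture(table, with_conflict=True)
        zones = make_grid(np.full((10, 10), 3))
        out = unresolved_stats(res, zones, year=2017)
        assert (out["NCells"] == 0).all()
        assert (out["Pct_Unresolved"] == 0.0).all()

    def test_unresolved_interior_counts_and_percent(self, table):
        # 20x20 wholly conflicting field inside a 100x100 single-zone grid
        nvc = np.full((100, 100), 7964, dtype=np.int32)
        cdl = np.full((100, 100), 1, dtype=np.int32)
        nvc[40:60, 40:60] = 7961
        res = merge(make_grid(nvc), make_grid(cdl), table)
        zones = make_grid(np.full((100, 100), 1001))
        out = unresolved_stats(res, zones, year=2017)
        assert len(out) == 1
        interior = 14 * 14  # pixels deeper than the 3-px window reach
        assert out.iloc[0]["NCells"] == interior
        assert out.iloc[0]["Pct_Unresolved"] == pytest.approx(interior / 10000 * 100)
        assert out.iloc[0]["MergedRaster_Class"] == -1001

    def test_conflict_free_zone_reports_zero(self, table):
        nvc = np.full((10, 10), 7964, dtype=np.int32)
        cdl = np.full((10, 10), 1, dtype=np.int32)
        nvc[2:4, 0:4] = 7961          # conflicts only in zone 1 (top half)
        cdl[2:4, 0:4] = NATURAL_CDL
        zones = np.full((10, 10), 1, dtype=np.int32)
        zones[5:, :] = 2
        res = merge(make_grid(nvc), make_grid(cdl), table)
        out = unresolved_stats(res, make_grid(zones), year=2017)
        zone2 = out[out["FIPS"] == 2].iloc[0]
        assert zone2["NCells"] == 0
        assert zone2["Pct_Unresolved"] == 0.0


class TestWeightedAccuracy:
    def test_single_class_identity(self):
        out = weighted_accuracy({1: 50}, [AccuracyRecord(1, users_acc=80.0,
                                                         producers_acc=70.0)])
        assert out["WtdUserAcc"] == pytest.approx(80.0)
        assert out["WtdProdAcc"] == pytest.approx(70.0)
        assert out["WithData_Pct"] == pytest.approx(100.0)

    def test_equal_weight_symmetry(self):
        recs = [AccuracyRecord(1, users_acc=40.0), AccuracyRecord(2, users_acc=60.0)]
        out = weighted_accuracy({1: 10, 2: 10}, recs)
        assert out["WtdUserAcc"] == pytest.approx(50.0)

    def test_no_reference_class_excluded_and_coverage_75(self):
        recs = [
            AccuracyRecord(1, users_acc=80.0),
            AccuracyRecord(2, has_reference=False),
        ]
        out = weighted_accuracy({1: 30, 2: 10}, recs)
        assert out["WtdUserAcc"] == pytest.approx(80.0)
        assert out["WithData_Pct"] == pytest.approx(75.0)

    def test_all_absent_accuracies_give_absent_output(self):
        out = weighted_accuracy({1: 5}, [AccuracyRecord(1, has_reference=False)])
        assert out["WtdUserAcc"] is None and out["WtdProdAcc"] is None
        assert out["WithData_Pct"] == 0.0

    def test_permutation_invariance_and_weight_concentration(self):
        recs = [AccuracyRecord(1, users_acc=30.0), AccuracyRecord(2, users_acc=90.0)]
        a = weighted_accuracy({1: 7, 2: 3}, recs)
        b = weighted_accuracy({2: 3, 1: 7}, list(reversed(recs)))
        assert a == b
        only = weighted_accuracy({1: 10, 2: 0}, recs)
        assert only["WtdUserAcc"] == pytest.approx(30.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            weighted_accuracy({1: -1}, [AccuracyRecord(1, users_acc=50.0)])

    def test_result_bounded_by_contributing_accuracies(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(1, 6)
            recs = [AccuracyRecord(i, users_acc=float(rng.uniform(0, 100)))
                    for i in range(n)]
            areas = {i: float(rng.uniform(0.1, 10)) for i in range(n)}
            out = weighted_accuracy(areas, recs)
            accs = [r.users_acc for r in recs]
            assert min(accs) - 1e-9 <= out["WtdUserAcc"] <= max(accs) + 1e-9


class TestSpanAccuracy:
    def test_all_natural_zone_equals_vegetation_only_accuracy(self, scheme):
        merged = make_grid(np.full((4, 4), NATURAL))
        zones = make_grid(np.full((4, 4), 1))
        out = span_accuracy(merged, zones, [],
                            [AccuracyRecord(NATURAL, users_acc=62.0,
                                            producers_acc=58.0)], scheme)
        assert out.iloc[0]["WtdUserAcc"] == pytest.approx(62.0)
        assert out.iloc[0]["WtdProdAcc"] == pytest.approx(58.0)

    def test_half_crop_half_natural_weighted_mean(self, scheme):
        merged = np.full((2, 4), NATURAL, dtype=np.int32)
        merged[:, :2] = -1  # corn from the crop layer
        zones = make_grid(np.full((2, 4), 1))
        out = span_accuracy(make_grid(merged), zones,
                            [AccuracyRecord(1, users_acc=80.0)],
                            [AccuracyRecord(NATURAL, users_acc=40.0)], scheme)
        assert out.iloc[0]["WtdUserAcc"] == pytest.approx(60.0)
        assert out.iloc[0]["NCells_FocalGroup"] == 8

    def test_unresolved_pixels_excluded_from_focal_area(self, scheme):
        merged = np.full((1, 4), -1001, dtype=np.int32)
        zones = make_grid(np.full((1, 4), 1))
        out = span_accuracy(make_grid(merged), zones, [], [], scheme)
        row = out.iloc[0]
        assert row["NCells_FocalGroup"] == 0
        assert row["WithData_PctFocalGroup"] == 0.0
        assert pd.isna(row["WtdUserAcc"])

    def test_class_without_record_treated_as_no_reference(self, scheme):
        merged = np.full((1, 4), NATURAL, dtype=np.int32)
        merged[0, 0] = -69  # grapes, no accuracy record supplied
        zones = make_grid(np.full((1, 4), 1))
        out = span_accuracy(make_grid(merged), zones, [],
                            [AccuracyRecord(NATURAL, users_acc=50.0)], scheme)
        assert out.iloc[0]["WithData_PctFocalGroup"] == pytest.approx(75.0)
        assert out.iloc[0]["WtdUserAcc"] == pytest.approx(50.0)


class TestJenks:
    def test_two_well_separated_clusters(self):
        edges = jenks_breaks([1, 2, 3, 10, 11, 12], k=2)
        assert edges == [1, 3, 12]
        assigned = jenks_assign([1, 2, 3, 10, 11, 12], edges)
        assert assigned.tolist() == [0, 0, 0, 1, 1, 1]

    def test_k1_single_class_spans_everything(self):
        assert jenks_breaks([4.0, 9.0, 2.0], k=1) == [2.0, 9.0]

    def test_k_equals_distinct_values_gives_zero_variance(self):
        vals = [3.0, 1.0, 2.0, 2.0]
        assert jenks_objective(vals, k=3) == pytest.approx(0.0)

    def test_k_above_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks([1, 1, 2], k=3)

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            vals = rng.integers(0, 40, size=n).astype(float)
            for k in range(1, min(4, np.unique(vals).size) + 1):
                assert jenks_objective(vals, k) == pytest.approx(
                    oracle_jenks_cost(vals, k), abs=1e-9
                )

    def test_edges_reproduce_optimal_cost_on_distinct_values(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            vals = rng.choice(200, size=n, replace=False).astype(float)
            k = int(rng.integers(1, 5))
            edges = jenks_breaks(vals, k)
            assert edges[0] == vals.min() and edges[-1] == vals.max()
            assert edges == sorted(edges)
            assert partition_cost(vals, edges) == pytest.approx(
                jenks_objective(vals, k), abs=1e-9
            )

    def test_objective_never_increases_with_k(self):
        vals = np.random.default_rng(5).uniform(0, 100, size=12)
        costs = [jenks_objective(vals, k) for k in range(1, 6)]
        assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))


class TestVerifyOutput:
    def _attrs(self):
        return [AttributeRow(NATURAL, "Natural"), AttributeRow(-1, "Corn"),
                AttributeRow(-1001, "Unresolved land cover")]

    def test_fresh_merge_passes(self, table):
        nvc = make_grid(np.full((5, 5), 7964))
        cdl = make_grid(np.full((5, 5), 1))
        res = merge(nvc, cdl, table)
        report = verify_output(res.merged, self._attrs(),
                               expected_extent=res.merged.extent,
                               expected_crs="EPSG:5070")
        assert report.passed

    def test_injected_value_fails_and_is_listed(self):
        grid = make_grid(np.full((3, 3), NATURAL))
        grid.values[1, 1] = 99999
        report = verify_output(grid, self._attrs())
        assert not report.passed
        assert 99999 in report.unexpected_values

    def test_altered_geotransform_fails_extent_check(self):
        grid = make_grid(np.full((3, 3), NATURAL))
        shifted = CategoricalGrid(values=grid.values, x_origin=900.0)
        report = verify_output(shifted, self._attrs(),
                               expected_extent=grid.extent)
        assert not report.passed and not report.extent_ok

    def test_wrong_crs_fails(self):
        grid = make_grid(np.full((3, 3), NATURAL))
        report = verify_output(grid, self._attrs(), expected_crs="EPSG:4326")
        assert not report.passed and not report.crs_ok

    def test_nodata_value_is_allowed(self):
        grid = make_grid(np.full((3, 3), NATURAL))
        grid.values[0, 0] = grid.nodata
        assert verify_output(grid, self._attrs()).passed
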