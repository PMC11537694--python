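"""Gap analysis: masking, classification, overlay, accounting, PA actions."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from priormap.geodata import (
    CategoricalLayer,
    ContinuousLayer,
    Grid,
    PolygonSet,
    binary_layer,
)
from priormap.gap import (
    PRIORITY_LEGEND,
    SuitabilityClasses,
    area_report,
    classify_suitability,
    exclusion_mask,
    model_agreement,
    overlay_priorities,
    pa_actions,
    percent_of,
    species_hotspots,
    ten_percent_training_threshold,
)


class TestExclusionMask:
    def test_empty_exclusions_give_zero_mask(self, grid5):
        lulc = CategoricalLayer(grid5, np.ones((5, 5), dtype=int))
        out = exclusion_mask(lulc, None, set())
        assert (out.values == 0).all()

    def test_city_cells_excluded(self, grid5):
        vals = np.ones((5, 5), dtype=int)
        vals[1, 1] = 2  # built-up class
        lulc = CategoricalLayer(grid5, vals)
        out = exclusion_mask(lulc, None, {2})
        assert out.values[1, 1] == 1 and out.values.sum() == 1

    def test_union_is_cellwise_or(self, grid5):
        vals = np.ones((5, 5), dtype=int)
        vals[0, 0] = 2
        lulc = CategoricalLayer(grid5, vals)
        road = np.zeros((5, 5), dtype=int)
        road[4, 4] = 1
        out = exclusion_mask(lulc, binary_layer(grid5, road), {2})
        expected = (vals == 2) | (road == 1)
        np.testing.assert_array_equal(out.values.astype(bool), expected)

    def test_unknown_code_warns(self, grid5):
        lulc = CategoricalLayer(grid5, np.ones((5, 5), dtype=int))
        with pytest.warns(UserWarning):
            exclusion_mask(lulc, None, {77})


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.10, 1),   # unsuitable
            (0.30, 2),   # less suitable
            (0.95, 4),   # highly suitable
            (0.25, 2),   # boundary to higher class
            (0.55, 3),
            (0.90, 3),   # highly requires > 0.90 strictly
            (0.9000001, 4),
        ],
    )
    def test_class_assignment(self, grid5, value, expected):
        rich = ContinuousLayer(grid5, np.full((5, 5), value))
        out = classify_suitability(rich)
        assert out.values[0, 0] == expected

    def test_masked_cells_forced_unsuitable(self, grid5):
        rich = ContinuousLayer(grid5, np.full((5, 5), 0.95))
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 2] = 1
        out = classify_suitability(rich, mask=binary_layer(grid5, mask))
        assert out.values[2, 2] == 1 and out.values[0, 0] == 4

    def test_out_of_range_values_rejected(self, grid5):
        rich = ContinuousLayer(grid5, np.full((5, 5), 1.2))
        with pytest.raises(ValueError):
            classify_suitability(rich)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            SuitabilityClasses(0.5, 0.4, 0.9)

    def test_ten_percent_training_threshold(self):
        vals = np.arange(1, 101) / 100.0
        t = ten_percent_training_threshold(
            ContinuousLayer(Grid(10, 10, 1.0), vals.reshape(10, 10)), vals
        )
        below = (vals < t).mean()
        assert below <= 0.10 < (vals <= t).mean() + 0.01
        assert t == pytest.approx(np.quantile(vals, 0.10))


class TestSpeciesHotspots:
    def test_all_unsuitable_gives_empty(self, grid5):
        cls = CategoricalLayer(grid5, np.ones((5, 5), dtype=int))
        assert (species_hotspots(cls).values == 0).all()

    def test_single_highly_suitable_cell(self, grid5):
        vals = np.ones((5, 5), dtype=int)
        vals[3, 3] = 4
        out = species_hotspots(CategoricalLayer(grid5, vals))
        assert int(out.values.sum()) == 1 and out.values[3, 3] == 1

    def test_hotspot_area_is_sum_of_suitable_class_areas(self, grid5):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 5, size=(5, 5))
        cls = CategoricalLayer(grid5, vals)
        hot = species_hotspots(cls)
        assert int(hot.values.sum()) == int((vals >= 2).sum())
        restricted = species_hotspots(cls, min_class=3)
        assert int(restricted.values.sum()) == int((vals >= 3).sum())


class TestOverlay:
    @pytest.mark.parametrize(
        "me,inv,inside,expected",
        [
            (1, 1, 1, 6),  # both models, inside PA -> priority inside core
            (1, 0, 0, 2),  # species model only, outside -> key priority
            (0, 0, 1, 7),  # neither model, inside -> over-protected
            (0, 1, 0, 1),
            (1, 1, 0, 3),
            (0, 1, 1, 4),
            (1, 0, 1, 5),
            (0, 0, 0, 0),
        ],
    )
    def test_tier_assignment(self, grid5, me, inv, inside, expected):
        shape = (5, 5)
        out = overlay_priorities(
            binary_layer(grid5, np.full(shape, me)),
            binary_layer(grid5, np.full(shape, inv)),
            binary_layer(grid5, np.full(shape, inside)),
        )
        assert (out.values == expected).all()

    def test_categories_partition_grid(self, grid30):
        rng = np.random.default_rng(1)
        me = binary_layer(grid30, rng.random((30, 30)) < 0.4)
        inv = binary_layer(grid30, rng.random((30, 30)) < 0.3)
        pa = binary_layer(grid30, rng.random((30, 30)) < 0.5)
        out = overlay_priorities(me, inv, pa)
        # every cell gets exactly one legend code; over-protected audit
        assert set(np.unique(out.values)) <= set(PRIORITY_LEGEND)
        over = out.values == 7
        assert np.all(pa.values[over] != 0)
        assert np.all(me.values[over] == 0) and np.all(inv.values[over] == 0)
        counts = {c: int((out.values == c).sum()) for c in PRIORITY_LEGEND}
        assert sum(counts.values()) == 900


class TestAreaReport:
    def test_worked_percentage_examples(self):
        total = 14.42e4  # study-area total, km2
        assert percent_of(14_764.14, total) == 10.24
        assert percent_of(7_858.45, total) == 5.45
        assert percent_of(4_536.65, 16_617.90) == 27.30
        assert percent_of(50_487.34, total) == 35.01
        assert percent_of(16_113.49, total) == 11.17

    def test_report_from_layer_counts_cells(self):
        grid = Grid(10, 10, 1000.0)  # 1 km cells
        vals = np.zeros((10, 10), dtype=int)
        vals[:2, :] = 1  # 20 cells
        rep = area_report(CategoricalLayer(grid, vals))
        row = rep[rep["code"] == 1].iloc[0]
        assert row["area_km2"] == pytest.approx(20.0)
        assert row["pct_of_total"] == 20.0
        assert rep["area_km2"].sum() == pytest.approx(100.0)

    def test_percentages_recompute_from_areas(self):
        grid = Grid(9, 9, 1000.0)
        rng = np.random.default_rng(2)
        rep = area_report(CategoricalLayer(grid, rng.integers(0, 4, (9, 9))))
        for _, row in rep.iterrows():
            assert row["pct_of_total"] == percent_of(row["area_km2"], 81.0)

    def test_empty_reference_rejected(self, grid5):
        layer = CategoricalLayer(grid5, np.zeros((5, 5), dtype=int))
        with pytest.raises(ValueError):
            area_report(layer, reference_areas={"pa": 0.0})

    def test_rounding_is_half_up(self):
        assert percent_of(5.0024, 100.0) == 5.00
        assert percent_of(5.005, 100.0) == 5.01
        assert percent_of(0.0, 100.0) == 0.0


class TestModelAgreement:
    def test_identical_maps_agree_fully(self, grid5):
        m = binary_layer(grid5, np.eye(5))
        out = model_agreement(m, m)
        assert all(v == 100.0 for v in out.values())

    def test_disjoint_maps_agree_zero(self, grid5):
        a = np.zeros((5, 5)); a[0, 0] = 1
        b = np.zeros((5, 5)); b[4, 4] = 1
        out = model_agreement(binary_layer(grid5, a), binary_layer(grid5, b))
        assert out["jaccard"] == 0.0 and out["overlap_coefficient"] == 0.0

    def test_partial_overlap_counts(self):
        grid = Grid(2, 2, 100.0, origin_y=200.0)
        a = binary_layer(grid, np.array([[1, 1], [0, 0]]))
        b = binary_layer(grid, np.array([[1, 0], [1, 0]]))
        out = model_agreement(a, b)
        assert out["jaccard"] == 33.33
        assert out["overlap_coefficient"] == 50.0

    def test_both_empty_reported_absent(self, grid5):
        z = binary_layer(grid5, np.zeros((5, 5)))
        assert all(v is None for v in model_agreement(z, z).values())


class TestPAActions:
    def priority_layer(self, grid, inside_code, frac, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.where(rng.random(grid.shape) < frac, inside_code, 7)
        return CategoricalLayer(grid, vals)

    def test_fully_priority_pa_binned_high(self, grid5):
        pri = CategoricalLayer(grid5, np.full((5, 5), 6, dtype=int))
        pas = PolygonSet([(1, "A", box(0, 0, 500, 500), {})])
        tab = pa_actions(pri, pas)
        assert tab.iloc[0]["proportion"] == 1.0 and tab.iloc[0]["bin"] == ">75%"

    def test_no_priority_pa_binned_low(self, grid5):
        pri = CategoricalLayer(grid5, np.full((5, 5), 7, dtype=int))
        pas = PolygonSet([(1, "A", box(0, 0, 500, 500), {})])
        assert pa_actions(pri, pas).iloc[0]["bin"] == "<25%"

    def test_half_priority_pa_binned_middle(self):
        grid = Grid(6, 10, 100.0, origin_y=600.0)
        vals = np.full((6, 10), 7, dtype=int)
        vals[:3, :] = 5  # 30 of 60 cells priority
        pri = CategoricalLayer(grid, vals)
        pas = PolygonSet([(1, "A", box(0, 0, 1000, 600), {})])
        tab = pa_actions(pri, pas)
        assert tab.iloc[0]["proportion"] == pytest.approx(0.5)
        assert tab.iloc[0]["bin"] == "25-75%"

    @pytest.mark.parametrize("n_priority,expected", [(15, "25-75%"), (45, ">75%"), (14, "<25%")])
    def test_bin_boundaries_go_to_higher_bin(self, n_priority, expected):
        grid = Grid(6, 10, 100.0, origin_y=600.0)
        vals = np.full((6, 10), 7, dtype=int)
        vals.ravel()[:n_priority] = 4
        pas = PolygonSet([(1, "A", box(0, 0, 1000, 600), {})])
        assert pa_actions(CategoricalLayer(grid, vals), pas).iloc[0]["bin"] == expected

    def test_pa_without_cells_flagged(self, grid5):
        pri = CategoricalLayer(grid5, np.full((5, 5), 7, dtype=int))
        tiny = box(0, 490, 6, 500)  # covers no cell center
        pas = PolygonSet([(1, "tiny", tiny, {})])
        tab = pa_actions(pri, pas)
        assert tab.iloc[0]["bin"] == "no-cells" and np.isnan(tab.iloc[0]["proportion"])
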