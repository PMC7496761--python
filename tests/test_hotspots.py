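"""Richness stacking, Jenks classification, change maps and area accounting."""

import itertools

import numpy as np
import pytest

from stacksdm.grid import GridSpec, area_layer_km2
from stacksdm.hotspots import (
    GAIN,
    LOSS,
    STABLE_SUITABLE,
    STABLE_UNSUITABLE,
    area_by_category,
    change_map,
    classify,
    group_summaries,
    jenks_breaks,
    net_change_pct,
    stack_richness,
)

GRID = GridSpec(6, 8, 0.0, 30.0, 1.0)


def _binary(rng, p=0.4):
    return (rng.random(GRID.shape) < p).astype(np.int8)


class TestRichness:
    def test_cellwise_sum(self, rng):
        b = {f"s{i}": _binary(rng) for i in range(3)}
        groups = {"s0": "zoobenthos", "s1": "zoobenthos", "s2": "zooplankton"}
        rm = stack_richness(b, groups, GRID, "present")
        np.testing.assert_array_equal(rm.counts, b["s0"] + b["s1"] + b["s2"])

    def test_empty_filter_all_zero(self, rng):
        b = {"s0": _binary(rng)}
        rm = stack_richness(b, {"s0": "zoobenthos"}, GRID, "present", "phytobenthos")
        assert rm.counts.sum() == 0

    def test_group_partition(self, rng):
        b = {f"s{i}": _binary(rng) for i in range(4)}
        groups = {"s0": "zoobenthos", "s1": "phytobenthos",
                  "s2": "zooplankton", "s3": "phytoplankton"}
        total = stack_richness(b, groups, GRID, "present").counts
        by_group = sum(
            stack_richness(b, groups, GRID, "present", g).counts
            for g in set(groups.values())
        )
        np.testing.assert_array_equal(total, by_group)

    def test_richness_conservation_in_area(self, rng):
        """Sum of richness x area equals the summed per-species suitable areas."""
        b = {f"s{i}": _binary(rng) for i in range(5)}
        groups = {k: "zoobenthos" for k in b}
        rm = stack_richness(b, groups, GRID, "present")
        areas = area_layer_km2(GRID)
        lhs = float((rm.counts * areas).sum())
        rhs = float(sum((m * areas).sum() for m in b.values()))
        assert lhs == pytest.approx(rhs, rel=1e-9)


def _brute_jenks(values, k):
    distinct, counts = np.unique(values, return_counts=True)
    m = len(distinct)
    best, best_cuts = np.inf, None
    for cuts in itertools.combinations(range(m - 1), k - 1):
        ssd = 0.0
        idx = [-1, *cuts, m - 1]
        for a, b in zip(idx[:-1], idx[1:]):
            seg = np.repeat(distinct[a + 1 : b + 1], counts[a + 1 : b + 1])
            ssd += float(((seg - seg.mean()) ** 2).sum())
        if ssd < best - 1e-12:
            best, best_cuts = ssd, cuts
    return best


def _achieved_ssd(values, breaks):
    cls = classify(values, breaks)
    return sum(
        float(((values[cls == c] - values[cls == c].mean()) ** 2).sum())
        for c in np.unique(cls)
    )


class TestJenks:
    def test_two_cluster_example(self):
        assert jenks_breaks(np.array([1, 2, 3, 10, 11, 12]), 2).tolist() == [3.0]

    def test_each_value_own_class(self):
        vals = np.array([1.0, 2.0, 5.0, 9.0])
        breaks = jenks_breaks(vals, 4)
        assert _achieved_ssd(vals, breaks) == 0.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(120):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, 5))
            vals = rng.integers(0, 9, n).astype(float)
            if len(np.unique(vals)) < k:
                continue
            breaks = jenks_breaks(vals, k)
            assert _achieved_ssd(vals, breaks) == pytest.approx(
                _brute_jenks(vals, k), abs=1e-9
            )

    def test_never_beaten_by_random_partitions(self, rng):
        vals = rng.integers(0, 15, 40).astype(float)
        k = 4
        breaks = jenks_breaks(vals, k)
        best = _achieved_ssd(vals, breaks)
        distinct = np.unique(vals)
        for _ in range(1000):
            cuts = np.sort(rng.choice(len(distinct) - 1, size=k - 1, replace=False))
            rand_breaks = distinct[cuts]
            assert best <= _achieved_ssd(vals, rand_breaks) + 1e-9

    def test_too_few_distinct_values_reduces_k(self):
        with pytest.warns(UserWarning, match="distinct"):
            breaks = jenks_breaks(np.array([1.0, 1.0, 2.0, 2.0]), 5)
        assert len(breaks) == 1

    def test_k_validation(self):
        with pytest.raises(ValueError):
            jenks_breaks(np.array([1.0, 2.0]), 1)


class TestAreaByCategory:
    def test_uniform_richness_single_class(self, rng):
        counts = np.zeros(GRID.shape, int)
        counts[2:4, 1:5] = 1
        rm = stack_richness({"s": counts.astype(np.int8)}, {"s": "zoobenthos"},
                            GRID, "present")
        df = area_by_category(rm, np.empty(0))
        areas = area_layer_km2(GRID)
        assert df.area_km2.sum() == pytest.approx(float(areas[counts > 0].sum()))

    def test_class_areas_partition_positive_cells(self, rng):
        b = {f"s{i}": _binary(rng, 0.5) for i in range(4)}
        rm = stack_richness(b, {k: "zoobenthos" for k in b}, GRID, "present")
        pos = rm.counts[rm.counts > 0]
        breaks = jenks_breaks(pos, min(3, len(np.unique(pos))))
        df = area_by_category(rm, breaks)
        areas = area_layer_km2(GRID)
        assert df.area_km2.sum() == pytest.approx(float(areas[rm.counts > 0].sum()),
                                                  rel=1e-9)

    def test_doubling_cell_size_quadruples_area(self):
        fine = GridSpec(6, 8, 0.0, 30.0, 1.0)
        coarse = GridSpec(6, 8, 0.0, 30.0, 2.0)
        counts = np.ones((6, 8), np.int8)
        a_fine = area_by_category(
            stack_richness({"s": counts}, {"s": "zoobenthos"}, fine, "present"),
            np.empty(0),
        ).area_km2.sum()
        a_coarse = area_by_category(
            stack_richness({"s": counts}, {"s": "zoobenthos"}, coarse, "present"),
            np.empty(0),
        ).area_km2.sum()
        assert a_coarse / a_fine == pytest.approx(4.0, rel=0.05)


class TestChange:
    def test_identical_maps_all_stable(self, rng):
        b = _binary(rng)
        cm = change_map(b, b, GRID)
        assert not np.any((cm.categories == GAIN) | (cm.categories == LOSS))

    def test_complement_flips_every_cell(self, rng):
        b = _binary(rng)
        cm = change_map(b, 1 - b, GRID)
        assert np.all((cm.categories == GAIN) | (cm.categories == LOSS))
        assert np.array_equal(cm.categories == LOSS, b.astype(bool))

    def test_categories_partition_mask(self, rng):
        bp, bf = _binary(rng), _binary(rng)
        cm = change_map(bp, bf, GRID)
        counts = {c: int((cm.categories == c).sum())
                  for c in (GAIN, LOSS, STABLE_SUITABLE, STABLE_UNSUITABLE)}
        assert sum(counts.values()) == GRID.n_rows * GRID.n_cols

    def test_no_change_gives_zero_pct(self, rng):
        b = _binary(rng)
        mask = np.ones(GRID.shape, bool)
        s = net_change_pct(b, b, mask, GRID)
        assert s.net_pct == 0.0

    def test_equal_area_doubling_gives_plus_hundred(self):
        # suitable cells all in one latitude row => exactly equal cell areas
        bp = np.zeros(GRID.shape, np.int8)
        bp[2, :2] = 1
        bf = np.zeros(GRID.shape, np.int8)
        bf[2, :4] = 1
        s = net_change_pct(bp, bf, np.ones(GRID.shape, bool), GRID)
        assert s.net_pct == pytest.approx(100.0)

    def test_zero_present_area_reported_undefined(self):
        z = np.zeros(GRID.shape, np.int8)
        f = np.ones(GRID.shape, np.int8)
        s = net_change_pct(z, f, np.ones(GRID.shape, bool), GRID)
        assert np.isnan(s.net_pct)

    def test_area_conservation_on_random_worlds(self, rng):
        """gain + loss + stable areas always re-sum to the extent area."""
        areas = area_layer_km2(GRID)
        for _ in range(50):
            bp, bf = _binary(rng), _binary(rng)
            mask = rng.random(GRID.shape) < 0.8
            s = net_change_pct(bp, bf, mask, GRID)
            total = s.gain_km2 + s.loss_km2 + s.stable_suitable_km2 + s.stable_unsuitable_km2
            assert total == pytest.approx(float(areas[mask].sum()), rel=1e-9)
            assert s.future_km2 == pytest.approx(s.present_km2 + s.gain_km2 - s.loss_km2)


class TestGroupSummaries:
    def _toy(self, rng):
        groups = {"a1": "zoobenthos", "a2": "zoobenthos", "b1": "zooplankton",
                  "c1": "phytobenthos", "d1": "phytoplankton"}
        data = {
            s: {sp: _binary(rng) for sp in groups}
            for s in ("present", "2050", "2100")
        }
        masks = {"global": np.ones(GRID.shape, bool),
                 "pan_arctic": np.zeros(GRID.shape, bool) | (np.arange(6)[:, None] >= 4)}
        return data, groups, masks

    def test_single_species_group_equals_species_summary(self, rng):
        data, groups, masks = self._toy(rng)
        table = group_summaries(data, groups, masks, GRID)
        row = table[(table.group == "zooplankton") & (table.extent == "global")
                    & (table.period == "present->2050")].iloc[0]
        direct = net_change_pct(data["present"]["b1"], data["2050"]["b1"],
                                masks["global"], GRID)
        assert row.net_pct == pytest.approx(direct.net_pct)

    def test_union_semantics_on_two_species(self, rng):
        data, groups, masks = self._toy(rng)
        table = group_summaries(data, groups, masks, GRID)
        row = table[(table.group == "zoobenthos") & (table.extent == "global")
                    & (table.period == "present->2100")].iloc[0]
        bp = (data["present"]["a1"] | data["present"]["a2"]).astype(bool)
        bf = (data["2100"]["a1"] | data["2100"]["a2"]).astype(bool)
        direct = net_change_pct(bp, bf, masks["global"], GRID)
        assert row.net_pct == pytest.approx(direct.net_pct)

    def test_full_coverage(self, rng):
        data, groups, masks = self._toy(rng)
        table = group_summaries(data, groups, masks, GRID)
        # 4 groups + all-species aggregate, 2 extents, 2 periods
        assert len(table) == 5 * 2 * 2

    def test_mean_aggregation_mode(self, rng):
        data, groups, masks = self._toy(rng)
        table = group_summaries(data, groups, masks, GRID, aggregation="mean")
        row = table[(table.group == "zoobenthos") & (table.extent == "global")
                    & (table.period == "present->2050")].iloc[0]
        per = [net_change_pct(data["present"][s], data["2050"][s],
                              masks["global"], GRID).net_pct for s in ("a1", "a2")]
        assert row.net_pct == pytest.approx(np.mean(per))
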