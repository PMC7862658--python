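"""Migration, filopodia, adhesion and mask statistics against oracles."""

import numpy as np
import pandas as pd
import pytest

from myotrack import metrics, synthetic
from myotrack.metrics import (
    AdhesionEvent,
    FilopodiaSet,
    NeighborSnapshot,
    SheetMask,
    adhesion_lifetimes,
    biased_angle,
    contact_distance,
    distance_on_x,
    filopodia_density,
    filopodia_orientation,
    gap_sizes_over_time,
    meandering_distance,
    neighbor_permanency,
    sheet_mask_metrics,
    track_speed_mean,
)


class TestDistanceOnX:
    def test_signed_subtraction(self):
        assert distance_on_x(np.array([5.0, 60.0, 135.0])) == 130.0
        assert distance_on_x(np.array([100.0, 70.0, 40.0])) == -60.0

    def test_invariant_under_interior_changes(self):
        a = np.array([0.0, 50.0, 20.0, 80.0])
        b = np.array([0.0, -3.0, 99.0, 80.0])
        assert distance_on_x(a) == distance_on_x(b)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            distance_on_x(np.array([1.0]))


def brute_force_knn(positions, k):
    n = len(positions)
    out = []
    for i in range(n):
        d = [(np.linalg.norm(positions[i] - positions[j]), j) for j in range(n) if j != i]
        d.sort()
        out.append({j for _, j in d[:k]})
    return out


class TestNeighborPermanency:
    def test_rigid_field_keeps_all_neighbors(self):
        rng = np.random.default_rng(0)
        p0 = rng.uniform(0, 100, size=(30, 2))
        theta = 0.3
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        p1 = p0 @ rot.T + np.array([40.0, -7.0])
        perm = neighbor_permanency(NeighborSnapshot(p0, p1))
        assert np.allclose(perm, 1.0)

    def test_constructed_half_retention(self):
        # cell 0 at origin; 6 near neighbors; 3 of them swap with far cells
        p0 = np.array(
            [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [1, 1], [-1, -1],
             [10, 0], [0, 10], [-10, 0], [20, 20]], dtype=float,
        )
        p1 = p0.copy()
        p1[[1, 2, 5]] = [[30, 30], [31, 31], [32, 32]]  # 3 neighbors leave
        p1[[7, 8, 9]] = [[1, 0], [0, 1], [1, 1]]  # replaced by far cells
        perm = neighbor_permanency(NeighborSnapshot(p0, p1))
        assert perm[0] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        p0 = rng.uniform(0, 50, size=(25, 2))
        p1 = p0 + rng.normal(0, 5, size=p0.shape)
        k = 6
        nn0 = brute_force_knn(p0, k)
        nn1 = brute_force_knn(p1, k)
        expected = np.array([len(a & b) / k for a, b in zip(nn0, nn1)])
        got = neighbor_permanency(NeighborSnapshot(p0, p1, k=k))
        assert np.allclose(got, expected)

    def test_too_few_cells_rejected(self):
        p = np.zeros((4, 2))
        with pytest.raises(ValueError):
            NeighborSnapshot(p, p, k=6)


class TestBiasedAngle:
    def test_pure_axis_drift_is_zero(self):
        pos = np.stack([np.arange(10.0), np.zeros(10)], axis=1)
        assert biased_angle(pos) == pytest.approx(0.0)

    def test_perpendicular_drift_is_ninety(self):
        pos = np.stack([np.zeros(10), np.arange(10.0)], axis=1)
        assert biased_angle(pos) == pytest.approx(90.0)

    def test_reverse_drift_is_one_eighty(self):
        pos = np.stack([-np.arange(10.0), np.zeros(10)], axis=1)
        assert biased_angle(pos) == pytest.approx(180.0)

    def test_isotropic_walk_averages_ninety(self):
        rng = np.random.default_rng(11)
        steps = rng.normal(size=(10_000, 2))
        pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        assert biased_angle(pos) == pytest.approx(90.0, abs=2.0)

    def test_speed_rescaling_invariance(self):
        rng = np.random.default_rng(12)
        steps = rng.normal(size=(200, 2))
        pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        assert biased_angle(pos) == pytest.approx(biased_angle(pos * 7.5))

    def test_stationary_track_flagged_nan(self):
        pos = np.zeros((5, 2))
        assert np.isnan(biased_angle(pos))


def projected_frame(y_by_track, radius=1.0, r_max=None):
    rows = []
    for tid, ys in y_by_track.items():
        for i, y in enumerate(ys):
            rows.append(
                {
                    "track_id": tid,
                    "time_min": 5.0 * i,
                    "x_corrected_um": 1.0 * i,
                    "y_unwrapped_um": y,
                    "radius_um": radius,
                }
            )
    return pd.DataFrame(rows)


class TestMeanderingDistance:
    def test_mean_line_track_is_zero(self):
        frame = projected_frame({"a": [3.0] * 10})
        res = meandering_distance(frame, r_max=1.0)
        assert res.dataset_median == 0.0

    def test_unit_deviation_at_maximal_radius(self):
        frame = projected_frame({"a": [1.0, -1.0] * 10}, radius=5.0)
        res = meandering_distance(frame, r_max=5.0)
        assert res.dataset_median == pytest.approx(1.0)

    def test_linear_in_radius_ratio(self):
        ys = {"a": list(np.sin(np.arange(20)))}
        full = meandering_distance(projected_frame(ys, radius=4.0), r_max=4.0)
        half = meandering_distance(projected_frame(ys, radius=2.0), r_max=4.0)
        assert half.dataset_median == pytest.approx(full.dataset_median / 2)
        assert np.allclose(
            half.per_track_median.values, full.per_track_median.values / 2
        )

    def test_x_mean_variant_includes_x_deviation(self):
        frame = projected_frame({"a": [0.0] * 10})
        literal = meandering_distance(frame, variant="literal")
        xmean = meandering_distance(frame, variant="x_mean")
        assert literal.dataset_median == 0.0
        assert xmean.dataset_median > 0.0  # x ramps, so x-deviation is nonzero
        assert xmean.variant == "x_mean"

    def test_missing_radius_rejected(self):
        frame = projected_frame({"a": [0.0, 1.0]})
        frame.loc[0, "radius_um"] = np.nan
        with pytest.raises(ValueError):
            meandering_distance(frame)


class TestTrackSpeedMean:
    def test_uniform_motion(self):
        t = np.arange(0, 50, 5.0)
        pos = np.stack([np.arange(10.0), np.zeros(10)], axis=1)
        assert track_speed_mean(t, pos) == pytest.approx(0.2)

    def test_stationary_is_zero(self):
        assert track_speed_mean(np.array([0.0, 5.0]), np.zeros((2, 2))) == 0.0

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 100, 20))
        pos = rng.uniform(0, 50, size=(20, 2))
        expected = np.linalg.norm(np.diff(pos, axis=0), axis=1).sum() / (t[-1] - t[0])
        assert track_speed_mean(t, pos) == pytest.approx(expected)

    def test_zero_elapsed_rejected(self):
        with pytest.raises(ValueError):
            track_speed_mean(np.array([5.0]), np.zeros((1, 2)))


class TestContactDistance:
    @staticmethod
    def track(times, xs, ys):
        return pd.DataFrame({"time_min": times, "x_um": xs, "y_um": ys})

    def test_stationary_pair_constant(self):
        a = self.track([0, 5, 10], [0, 0, 0], [0, 0, 0])
        b = self.track([0, 5, 10], [10, 10, 10], [0, 0, 0])
        out = contact_distance(a, b)
        assert np.allclose(out["distance_um"], 10.0)

    def test_identical_tracks_zero(self):
        a = self.track([0, 5], [1, 2], [3, 4])
        assert np.allclose(contact_distance(a, a)["distance_um"], 0.0)

    def test_only_shared_timepoints_used(self):
        a = self.track([0, 5, 10], [0, 1, 2], [0, 0, 0])
        b = self.track([5, 10, 15], [4, 5, 6], [0, 0, 0])
        out = contact_distance(a, b)
        assert list(out["time_min"]) == [5, 10]
        assert np.allclose(out["distance_um"], [3.0, 3.0])

    def test_disjoint_times_rejected(self):
        a = self.track([0], [0], [0])
        b = self.track([5], [0], [0])
        with pytest.raises(ValueError):
            contact_distance(a, b)


class TestFilopodia:
    def test_cardinal_bearings(self):
        fset = FilopodiaSet(
            center_of_mass=[2.0, 3.0],
            tips=[[3.0, 3.0], [2.0, 4.0], [1.0, 3.0], [2.0, 2.0]],
        )
        angles, _ = filopodia_orientation(fset)
        assert np.allclose(sorted(angles), [0.0, 90.0, 180.0, 270.0])

    def test_uniform_degree_fan_fills_bins_evenly(self):
        deg = np.arange(360.0)
        tips = np.stack([np.cos(np.radians(deg)), np.sin(np.radians(deg))], axis=1)
        _, counts = filopodia_orientation(FilopodiaSet([0.0, 0.0], tips))
        assert np.all(counts == 30)

    def test_coincident_tip_skipped(self):
        fset = FilopodiaSet([0.0, 0.0], [[0.0, 0.0], [1.0, 0.0]])
        angles, _ = filopodia_orientation(fset)
        assert len(angles) == 1

    def test_density_front_vs_rear(self):
        # 10 tips ahead of (smaller x than) the center on a 5 um front edge
        tips = [[-1.0, float(i)] for i in range(10)] + [[1.0, 0.0]] * 4
        fset = FilopodiaSet([0.0, 0.0], tips, front_edge_um=5.0, rear_edge_um=8.0)
        front, rear = filopodia_density(fset)
        assert front == pytest.approx(2.0)
        assert rear == pytest.approx(0.5)

    def test_ties_go_to_rear(self):
        fset = FilopodiaSet(
            [0.0, 0.0], [[0.0, 1.0], [0.0, -1.0]], front_edge_um=5.0, rear_edge_um=5.0
        )
        front, rear = filopodia_density(fset)
        assert front == 0.0
        assert rear == pytest.approx(0.4)

    def test_missing_edge_lengths_rejected(self):
        fset = FilopodiaSet([0.0, 0.0], [[1.0, 0.0]])
        with pytest.raises(ValueError):
            filopodia_density(fset)


class TestAdhesionLifetimes:
    def test_simple_lifetime(self):
        lifetimes, summary = adhesion_lifetimes(
            [AdhesionEvent("a", 0.0, 10.0, "free_edge")]
        )
        assert lifetimes["lifetime_min"].iloc[0] == 10.0
        assert summary.set_index("edge_class").loc["free_edge", "n"] == 1

    def test_censored_excluded_but_counted(self):
        events = [
            AdhesionEvent("a", 0.0, 10.0, "free_edge"),
            AdhesionEvent("b", 5.0, 120.0, "free_edge", censored=True),
        ]
        lifetimes, summary = adhesion_lifetimes(events)
        assert len(lifetimes) == 1
        row = summary.set_index("edge_class").loc["free_edge"]
        assert row["n"] == 1 and row["n_censored"] == 1

    def test_death_before_birth_rejected(self):
        with pytest.raises(ValueError):
            AdhesionEvent("a", 10.0, 5.0, "free_edge")

    def test_ratio_recovery_on_synthetic_events(self):
        events = synthetic.generate_adhesion_events(
            n_per_class=1000, mean_lifetime_free_min=10.0,
            mean_lifetime_cell_cell_min=5.0, movie_length_min=200.0, seed=9,
        )
        _, summary = adhesion_lifetimes(events)
        s = summary.set_index("edge_class")
        ratio = s.loc["free_edge", "mean_min"] / s.loc["cell_cell_edge", "mean_min"]
        assert ratio == pytest.approx(2.0, rel=0.10)


def square_hole_mask(hole=5, shape=(40, 40), px=1.0, cells=4):
    m = np.ones(shape, dtype=bool)
    m[10 : 10 + hole, 12 : 12 + hole] = False
    return SheetMask(m, pixel_size_um=px, cell_count=cells)


def flood_fill_gaps(mask):
    """Brute-force 8-connected hole labelling by BFS, excluding blobs that
    touch the border."""
    gaps = ~mask
    seen = np.zeros_like(gaps, dtype=bool)
    comps = []
    h, w = gaps.shape
    for i in range(h):
        for j in range(w):
            if gaps[i, j] and not seen[i, j]:
                stack, comp, touches = [(i, j)], [], False
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    comp.append((a, b))
                    if a in (0, h - 1) or b in (0, w - 1):
                        touches = True
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if 0 <= na < h and 0 <= nb < w and gaps[na, nb] and not seen[na, nb]:
                                seen[na, nb] = True
                                stack.append((na, nb))
                if not touches:
                    comps.append(comp)
    return comps


class TestSheetMaskMetrics:
    def test_square_hole(self):
        out = sheet_mask_metrics(square_hole_mask(hole=5))
        assert out["gap_count"] == 1
        assert out["free_edge_um"] == pytest.approx(20.0)
        assert out["area_per_cell_um2"] == pytest.approx((1600 - 25) / 4)

    def test_full_foreground(self):
        m = SheetMask(np.ones((30, 30), dtype=bool), 1.0, cell_count=3)
        out = sheet_mask_metrics(m)
        assert out["gap_count"] == 0
        assert out["free_edge_um"] == 0.0

    def test_free_edge_scales_with_pixel_size(self):
        out1 = sheet_mask_metrics(square_hole_mask(px=1.0))
        out2 = sheet_mask_metrics(square_hole_mask(px=0.5))
        assert out1["free_edge_um"] == pytest.approx(2 * out2["free_edge_um"])

    def test_translation_invariance(self):
        m1 = np.ones((50, 50), dtype=bool)
        m1[5:9, 5:11] = False
        m2 = np.roll(np.roll(m1, 13, axis=0), 21, axis=1)
        o1 = sheet_mask_metrics(SheetMask(m1, 1.0))
        o2 = sheet_mask_metrics(SheetMask(m2, 1.0))
        assert o1["gap_count"] == o2["gap_count"]
        assert o1["free_edge_um"] == o2["free_edge_um"]

    def test_random_masks_match_flood_fill_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            m = np.ones((30, 30), dtype=bool)
            for _ in range(rng.integers(1, 6)):
                r, c = rng.integers(2, 24, size=2)
                hh, ww = rng.integers(1, 5, size=2)
                m[r : r + hh, c : c + ww] = False
            mask = SheetMask(m, 1.0)
            comps = flood_fill_gaps(mask.mask)
            out = sheet_mask_metrics(mask)
            assert out["gap_count"] == len(comps)
            areas = sorted(len(c) for c in comps)
            assert sorted(metrics.gap_areas(mask).tolist()) == pytest.approx(areas)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            SheetMask(np.arange(9).reshape(3, 3), 1.0)


class TestGapSizesOverTime:
    def test_threshold_rule(self):
        def mask_with_area(area_px):
            m = np.ones((40, 40), dtype=bool)
            h = {15: (3, 5), 25: (5, 5)}[area_px]
            m[10 : 10 + h[0], 10 : 10 + h[1]] = False
            return SheetMask(m, 1.0)

        out = gap_sizes_over_time([mask_with_area(15), mask_with_area(25)])
        assert out["total_gap_area_um2"].tolist() == [0.0, 25.0]

    def test_monotone_growth_schedule(self):
        schedule = [
            [synthetic.HoleSpec(10, 10, a)] for a in (0, 9, 25, 49, 100)
        ]
        masks, true_areas = synthetic.generate_sheet_masks(
            schedule, shape=(60, 60)
        )
        out = gap_sizes_over_time(masks)
        assert np.all(np.diff(out["total_gap_area_um2"]) >= 0)
        # reported areas equal the generator's measured truth above threshold
        for total, areas in zip(out["total_gap_area_um2"], true_areas):
            assert total == pytest.approx(areas[areas > 20.0].sum())

    def test_mixed_pixel_sizes_rejected(self):
        a = SheetMask(np.ones((5, 5), dtype=bool), 1.0)
        b = SheetMask(np.ones((5, 5), dtype=bool), 2.0)
        with pytest.raises(ValueError):
            gap_sizes_over_time([a, b])
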