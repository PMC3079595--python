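"""Perceptual segmentation-quality energy: distance-weighted errors, matching."""

import numpy as np
import pytest

from historoi.fixtures import FixtureSpec, generate_fixture, micro_image
from historoi.quality import (
    DB_FLOOR,
    DistanceWeighting,
    added_background,
    boundary_inaccuracy,
    fg_quality,
    mask_partition,
    match_regions,
    missing_foreground,
    oversegmentation_error,
    partition_masks,
    total_energy,
    undersegmentation_error,
)
from oracles import brute_force_distance

UNIT = DistanceWeighting(slope=1.0, offset=0.0, d_max=20.0)  # w(i) = i


def square_mask():
    _, mask = micro_image("square3in8")
    return mask.astype(bool)


class TestMissingForeground:
    def test_perfect_prediction_scores_zero(self):
        g = square_mask()
        assert missing_foreground(g, g, UNIT) == 0.0

    def test_missing_corner_pixel_weighted_by_unit_distance(self):
        g = square_mask()
        c = g.copy()
        c[2, 2] = False
        got = missing_foreground(g, c, UNIT)
        # confirm with an exhaustive distance search on the 8x8 grid
        assert brute_force_distance(c, 2, 2) == 1.0
        assert got == 1.0

    def test_overprediction_costs_nothing_here(self):
        g = square_mask()
        c = np.ones_like(g)
        assert missing_foreground(g, c, UNIT) == 0.0

    def test_empty_prediction_uses_max_distance_convention(self):
        g = square_mask()
        c = np.zeros_like(g)
        w = DistanceWeighting(slope=1.0, offset=1.0, d_max=20.0)
        assert missing_foreground(g, c, w) == 9 * w.max_weight


class TestAddedBackground:
    def test_perfect_prediction_scores_zero(self):
        g = square_mask()
        assert added_background(g, g, UNIT) == 0.0

    def test_one_adjacent_extra_pixel_costs_unit_weight(self):
        g = square_mask()
        c = g.copy()
        c[1, 2] = True  # touches the top edge of the square
        assert brute_force_distance(g, 1, 2) == 1.0
        assert added_background(g, c, UNIT) == 1.0

    def test_underprediction_costs_nothing_here(self):
        g = square_mask()
        c = g.copy()
        c[2, 2] = False
        assert added_background(g, c, UNIT) == 0.0

    def test_weights_match_exhaustive_distances(self, rng):
        g = rng.random((8, 8)) > 0.6
        c = rng.random((8, 8)) > 0.6
        if not g.any():
            g[4, 4] = True
        w = DistanceWeighting(slope=2.0, offset=1.0, d_max=5.0)
        expected = sum(
            w.offset + w.slope * min(brute_force_distance(g, y, x), w.d_max)
            for y, x in zip(*np.nonzero(c & ~g)))
        assert added_background(g, c, w) == pytest.approx(expected)


class TestFgQuality:
    def test_identity_hits_db_floor(self):
        g = square_mask()
        q = fg_quality(g, g)
        assert q.raw == 0.0 and q.normalized == 0.0
        assert q.db == pytest.approx(DB_FLOOR)

    def test_empty_prediction_closed_form(self):
        g = square_mask()
        c = np.zeros_like(g)
        q = fg_quality(g, c)
        assert q.normalized == pytest.approx(9.0 / 64.0)

    def test_distant_error_costs_more_than_border_error(self):
        g = square_mask()
        near = g.copy()
        near[1, 3] = True
        far = g.copy()
        far[7, 7] = True
        assert fg_quality(g, far).raw > fg_quality(g, near).raw


class TestMatchRegions:
    def test_identical_partitions_match_perfectly(self):
        _, labels = micro_image("quadrants4")
        pairs, unc_c, unc_g = match_regions(partition_masks(labels), labels)
        assert len(pairs) == 4 and not unc_c and not unc_g

    def test_split_region_pairs_with_larger_overlap(self):
        g = [np.zeros((6, 6), dtype=bool)]
        g[0][:, :5] = True  # 30 pixels
        labels = np.zeros((6, 6), dtype=int)
        labels[:, 3:] = 1  # region 0 overlap 18, region 1 overlap 12
        pairs, unc_c, unc_g = match_regions(g, labels)
        assert pairs == [(0, 0, 18)]
        assert unc_c == [1] and unc_g == []

    def test_conflicting_ground_truths_resolved_by_overlap(self):
        g1 = np.zeros((6, 6), dtype=bool)
        g1[:4, :] = True  # overlap 24 with the single region
        g2 = np.zeros((6, 6), dtype=bool)
        g2[4:, :] = True  # overlap 12
        labels = np.zeros((6, 6), dtype=int)
        pairs, unc_c, unc_g = match_regions([g1, g2], labels)
        assert pairs == [(0, 0, 24)]
        assert unc_g == [1]


class TestErrorTerms:
    def test_boundary_inaccuracy_is_sum_of_pair_qualities(self):
        g = square_mask()
        c = g.copy()
        c[2, 2] = False
        assert boundary_inaccuracy([(g, c)]) == pytest.approx(fg_quality(g, c).raw)
        assert boundary_inaccuracy([]) == 0.0

    def test_uncoupled_prediction_penalty_closed_form(self):
        w = DistanceWeighting()
        region = np.zeros((8, 8), dtype=bool)
        region[5:7, 5:7] = True
        assert oversegmentation_error([region], (8, 8), w) == 4 * w.max_weight
        assert oversegmentation_error([], (8, 8), w) == 0.0

    def test_penalties_add_over_disjoint_regions(self):
        w = DistanceWeighting()
        r1 = np.zeros((8, 8), dtype=bool)
        r1[0, 0] = True
        r2 = np.zeros((8, 8), dtype=bool)
        r2[7, 7] = True
        both = oversegmentation_error([r1, r2], (8, 8), w)
        assert both == oversegmentation_error([r1], (8, 8), w) + \
            oversegmentation_error([r2], (8, 8), w)

    def test_under_and_over_segmentation_are_mirrors(self):
        w = DistanceWeighting()
        region = np.zeros((8, 8), dtype=bool)
        region[2:5, 3:6] = True
        assert undersegmentation_error([region], (8, 8), w) == \
            oversegmentation_error([region], (8, 8), w)


class TestTotalEnergy:
    def test_identity_on_micro_catalogue(self):
        for name in ("uniform4", "halves4", "quadrants4"):
            _, labels = micro_image(name)
            report = total_energy(partition_masks(labels), labels)
            assert report.energy == 0.0
            assert report.db_total == pytest.approx(DB_FLOOR)

    def test_identity_on_random_fixture_partitions(self):
        for seed in range(10):
            spec = FixtureSpec(width=64, height=64, n_islets=1,
                               islet_radius_range=(10, 14), seed=seed)
            _, mask = generate_fixture(spec)
            partition = mask_partition(mask)
            assert total_energy(partition, partition).energy == 0.0

    def test_any_single_flip_strictly_positive(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[2:5, 2:5] = 1
        partition = partition_masks(labels)
        for y in range(6):
            for x in range(6):
                flipped = labels.copy()
                flipped[y, x] = 1 - flipped[y, x]
                assert total_energy(partition, flipped).energy > 0.0

    def test_energy_components_sum(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[2:5, 2:5] = 1
        pred = labels.copy()
        pred[0, 0] = 2  # an extra spurious region
        report = total_energy(partition_masks(labels), pred)
        assert report.energy == pytest.approx(report.e_bl + report.e_ov + report.e_un)
        assert report.db_total <= 0.0 and np.isfinite(report.db_total)

    def test_growing_error_set_never_decreases_energy(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[2:5, 2:5] = 1
        partition = partition_masks(labels)
        pred = labels.copy()
        energies = [total_energy(partition, pred).energy]
        for y, x in [(2, 2), (2, 3), (3, 2)]:  # nested corruption of the square
            pred[y, x] = 0
            energies.append(total_energy(partition, pred).energy)
        assert all(b >= a for a, b in zip(energies, energies[1:]))


def test_distance_weighting_validation():
    with pytest.raises(ValueError):
        DistanceWeighting(slope=0.0).validate()
    with pytest.raises(ValueError):
        DistanceWeighting(d_max=-1.0).validate()
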