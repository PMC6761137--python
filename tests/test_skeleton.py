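"""Skeletonization, branch-point detection, subtraction and measurement."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from tjquant import (
    detect_junctions,
    measure_branches,
    remove_junctions,
    skeletonize,
)
from tjquant.skeleton import (
    JunctionSet,
    _junctions_hit_or_miss_literal,
    _junctions_lut,
    _junctions_neighbor_count,
)

from conftest import (
    as_mask,
    as_skeleton,
    brute_force_junctions,
    make_line,
    make_loop,
    make_plus,
    random_blob_mask,
    random_sparse_skeleton,
)

EIGHT = np.ones((3, 3), dtype=int)


def n_components(grid):
    return ndi.label(grid, structure=EIGHT)[1]


class TestSkeletonize:
    def test_thick_bar_thins_to_spanning_curve(self):
        bar = np.zeros((9, 24), dtype=bool)
        bar[3:6, 2:22] = True
        skel = skeletonize(as_mask(bar)).values
        assert skel.sum() > 0 and np.all(bar | ~skel)  # subset of the mask
        assert n_components(skel) == 1
        cols = np.nonzero(skel.any(axis=0))[0]
        assert cols.max() - cols.min() >= 17  # spans (almost) the bar extent
        # thinness: no 2x2 block fully foreground
        assert not (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any()

    def test_single_pixel_is_fixed_point(self):
        grid = np.zeros((7, 7), dtype=bool)
        grid[3, 3] = True
        np.testing.assert_array_equal(skeletonize(as_mask(grid)).values, grid)

    def test_random_blobs_preserve_components_subset_thinness(self, rng):
        for _ in range(50):
            mask = random_blob_mask(rng)
            skel = skeletonize(as_mask(mask)).values
            assert np.all(mask | ~skel)
            assert n_components(skel) == n_components(mask)
            assert not (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any()


class TestDetectJunctions:
    def test_plus_centre_cluster(self):
        """At a 4-way crossing the centre and its 4 orthogonal neighbours all
        have >=3 neighbours (the arms touch diagonally), forming one cluster."""
        skel = as_skeleton(make_plus(5))
        junctions = detect_junctions(skel)
        assert len(junctions) == 5
        assert junctions.n_clusters() == 1
        centre = make_plus(5).shape[0] // 2
        assert [centre, centre] in junctions.coords.tolist()

    def test_straight_line_has_none(self):
        assert len(detect_junctions(as_skeleton(make_line(12)))) == 0

    def test_closed_loop_has_none(self):
        assert len(detect_junctions(as_skeleton(make_loop()))) == 0

    def test_all_512_neighbourhoods_equivalent(self):
        """Catalogue hit-or-miss, literal scipy hit-or-miss and neighbour
        counting agree on every possible 3x3 configuration."""
        for code in range(512):
            patch = np.zeros((5, 5), dtype=bool)
            patch[1:4, 1:4] = ((code >> np.arange(9)) & 1).reshape(3, 3).astype(bool)
            lut = _junctions_lut(patch)
            literal = _junctions_hit_or_miss_literal(patch)
            counted = _junctions_neighbor_count(patch)
            np.testing.assert_array_equal(lut, literal)
            np.testing.assert_array_equal(lut, counted)
            # centre pixel verdict matches first principles
            centre_on = bool(patch[2, 2])
            n_neighbors = int(patch[1:4, 1:4].sum()) - int(centre_on)
            assert lut[2, 2] == (centre_on and n_neighbors >= 3)

    def test_random_skeletons_match_brute_force(self, rng):
        for _ in range(200):
            skel = random_sparse_skeleton(rng)
            expected = brute_force_junctions(skel)
            got = detect_junctions(as_skeleton(skel)).as_mask(skel.shape)
            np.testing.assert_array_equal(got, expected)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            detect_junctions(as_skeleton(make_plus()), method="guesswork")


class TestRemoveJunctions:
    def test_plus_minus_centre_bookkeeping(self):
        plus = make_plus(5)  # 21 px
        centre = plus.shape[0] // 2
        out = remove_junctions(
            as_skeleton(plus), JunctionSet(coords=[[centre, centre]])
        ).values
        assert out.sum() == 20
        assert not out[centre, centre]

    def test_empty_junction_set_is_identity(self):
        plus = make_plus(4)
        out = remove_junctions(as_skeleton(plus), JunctionSet(coords=np.empty((0, 2))))
        np.testing.assert_array_equal(out.values, plus)

    def test_off_skeleton_junction_rejected(self):
        with pytest.raises(ValueError, match="on the skeleton"):
            remove_junctions(as_skeleton(make_plus(3)), JunctionSet(coords=[[0, 0]]))

    def test_random_pixel_counts_exact(self, rng):
        for _ in range(25):
            skel = random_sparse_skeleton(rng)
            junctions = detect_junctions(as_skeleton(skel))
            out = remove_junctions(as_skeleton(skel), junctions).values
            assert out.sum() == skel.sum() - len(junctions)


class TestMeasureBranches:
    def test_plus_after_detected_junction_removal(self):
        """Removing the 5-px junction cluster of a 5-px-armed plus leaves 4
        separated arms of 4 px each."""
        skel = as_skeleton(make_plus(5), pixel_size=0.2)
        branches = remove_junctions(skel, detect_junctions(skel))
        segments = measure_branches(branches, min_branch_px=1)
        assert len(segments) == 4
        assert all(s.pixel_count == 4 for s in segments.segments)
        assert all(s.length_um == pytest.approx(0.8) for s in segments.segments)

    def test_empty_mask(self):
        segments = measure_branches(as_mask(np.zeros((8, 8), dtype=bool)))
        assert len(segments) == 0 and segments.discarded_px == 0

    def test_conservation_on_random_inputs(self, rng):
        for _ in range(25):
            mask = random_sparse_skeleton(rng, shape=(32, 32))
            segments = measure_branches(as_mask(mask), min_branch_px=3)
            assert segments.total_pixels + segments.discarded_px == mask.sum()

    def test_min_branch_monotonicity(self, rng):
        mask = as_mask(random_sparse_skeleton(rng, shape=(48, 48), p=0.25))
        counts = [len(measure_branches(mask, min_branch_px=k)) for k in (1, 2, 4, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_raster_order_labelling_deterministic(self, rng):
        mask = as_mask(random_sparse_skeleton(rng, shape=(32, 32), p=0.22))
        seg_a = measure_branches(mask, min_branch_px=1)
        seg_b = measure_branches(mask, min_branch_px=1)
        firsts = [tuple(min(map(tuple, s.coords))) for s in seg_a.segments]
        assert firsts == sorted(firsts)  # ids follow raster order of first pixel
        for s1, s2 in zip(seg_a.segments, seg_b.segments):
            np.testing.assert_array_equal(s1.coords, s2.coords)

    def test_geodesic_lengths_on_straight_and_diagonal_lines(self):
        horizontal = np.zeros((5, 12), dtype=bool)
        horizontal[2, 1:11] = True  # 10 px, 9 orthogonal steps
        seg = measure_branches(as_mask(horizontal, pixel_size=0.5)).segments[0]
        assert seg.length_um == pytest.approx(5.0)
        assert seg.geodesic_length_um == pytest.approx(9 * 0.5)

        diagonal = np.eye(10, dtype=bool)
        seg = measure_branches(as_mask(diagonal, pixel_size=1.0)).segments[0]
        assert seg.geodesic_length_um == pytest.approx(9 * np.sqrt(2))


class TestClosedLoop:
    def test_loop_is_one_segment_with_no_junctions(self):
        loop = make_loop()
        skel = as_skeleton(loop)
        junctions = detect_junctions(skel)
        assert len(junctions) == 0
        segments = measure_branches(remove_junctions(skel, junctions))
        assert len(segments) == 1
        assert segments.segments[0].pixel_count == loop.sum()


class TestFullConservation:
    def test_skeleton_equals_junctions_plus_segments_plus_discards(self, rng):
        """|skeleton| = |junctions| + sum(pixel_count) + discarded, end to end."""
        for _ in range(50):
            mask = random_blob_mask(rng)
            skel = skeletonize(as_mask(mask))
            junctions = detect_junctions(skel)
            branches = remove_junctions(skel, junctions)
            segments = measure_branches(branches, min_branch_px=3)
            assert (
                skel.values.sum()
                == len(junctions) + segments.total_pixels + segments.discarded_px
            )
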