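"""Border following against brute-force boundary oracles, plus edge splitting."""

import numpy as np
import pytest

from cornoct import (
    BinaryImage,
    Contour,
    CornoctError,
    NoiseModel,
    binarize,
    generate_phantom,
    min_bounding_rect,
    select_corneal_contour,
    split_edges,
    trace_boundaries,
)
from cornoct.fitting import evaluate_curve

from oracles import brute_force_boundaries, random_binary_image


def _adjacent(p, q):
    return max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1


def assert_matches_oracle(img):
    """Traced boundary point sets must equal the brute-force sets exactly."""
    contours = trace_boundaries(BinaryImage(img))
    oracle_outers, oracle_holes = brute_force_boundaries(img)

    traced_outers = sorted(
        (c.point_set() for c in contours if c.boundary_type == "outer"), key=sorted
    )
    traced_holes = sorted(
        (c.point_set() for c in contours if c.boundary_type == "hole"), key=sorted
    )
    assert traced_outers == sorted(oracle_outers.values(), key=sorted)
    assert traced_holes == sorted((pts for _, pts in oracle_holes), key=sorted)
    # one traced boundary per brute-force boundary
    assert len(contours) == len(oracle_outers) + len(oracle_holes)
    return contours


class TestTraceBoundaries:
    def test_single_pixel_gives_one_point_outer_contour(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 3] = 1
        contours = trace_boundaries(BinaryImage(img))
        assert len(contours) == 1
        c = contours[0]
        assert c.boundary_type == "outer"
        assert c.points == [(2, 3)]
        assert c.parent is None

    def test_solid_3x3_square_has_8_point_perimeter_and_no_hole(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[1:4, 1:4] = 1
        contours = trace_boundaries(BinaryImage(img))
        assert len(contours) == 1
        c = contours[0]
        assert c.boundary_type == "outer"
        perimeter = {(r, cc) for r in range(1, 4) for cc in range(1, 4)} - {(2, 2)}
        assert c.point_set() == frozenset(perimeter)
        assert len(set(c.points)) == 8

    def test_5x5_square_with_center_hole_has_hole_child(self):
        img = np.zeros((7, 7), dtype=np.uint8)
        img[1:6, 1:6] = 1
        img[3, 3] = 0
        contours = assert_matches_oracle(img)
        outer = [c for c in contours if c.boundary_type == "outer"]
        holes = [c for c in contours if c.boundary_type == "hole"]
        assert len(outer) == 1 and len(holes) == 1
        assert holes[0].parent == outer[0].sequence_number

    def test_all_zero_image_yields_no_contours(self):
        assert trace_boundaries(BinaryImage(np.zeros((4, 4), dtype=np.uint8))) == []

    def test_full_frame_image_is_single_outer_boundary(self):
        img = np.ones((4, 6), dtype=np.uint8)
        contours = assert_matches_oracle(img)
        assert [c.boundary_type for c in contours] == ["outer"]
        assert contours[0].parent is None

    def test_contours_are_closed_and_8_connected(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            img = random_binary_image(rng, max_side=24)
            for c in trace_boundaries(BinaryImage(img)):
                pts = c.points
                if len(pts) == 1:
                    continue
                for p, q in zip(pts, pts[1:]):
                    assert _adjacent(p, q)
                assert _adjacent(pts[0], pts[-1])

    def test_random_images_match_bruteforce_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            assert_matches_oracle(random_binary_image(rng, max_side=24))

    def test_hole_parents_are_enclosing_outer_contours(self):
        rng = np.random.default_rng(55)
        from scipy import ndimage

        for _ in range(40):
            img = random_binary_image(rng, max_side=20)
            contours = trace_boundaries(BinaryImage(img))
            by_seq = {c.sequence_number: c for c in contours}
            lab1, _ = ndimage.label(img != 0, structure=np.ones((3, 3), int))
            for c in contours:
                if c.boundary_type != "hole":
                    continue
                parent = by_seq[c.parent]
                assert parent.boundary_type == "outer"
                # hole boundary pixels belong to the parent's 1-component
                labels = {lab1[p] for p in c.points} | {lab1[p] for p in parent.points}
                assert len(labels) == 1


class TestSelectCornealContour:
    def _mk(self, n, seq):
        return Contour(points=[(0, i) for i in range(n)], boundary_type="outer",
                       sequence_number=seq)

    def test_single_contour_selected(self):
        c = self._mk(5, 2)
        assert select_corneal_contour([c]) is c

    def test_longest_contour_wins(self):
        short, long_ = self._mk(10, 2), self._mk(200, 3)
        assert select_corneal_contour([short, long_]) is long_

    def test_tie_broken_by_smaller_sequence_number(self):
        a, b = self._mk(50, 2), self._mk(50, 3)
        assert select_corneal_contour([b, a]) is a

    def test_no_outer_contours_is_error(self):
        hole = Contour(points=[(0, 0)], boundary_type="hole", sequence_number=2)
        with pytest.raises(CornoctError):
            select_corneal_contour([hole])


class TestMinBoundingRect:
    def test_single_point(self):
        c = Contour(points=[(4, 7)], boundary_type="outer", sequence_number=2)
        assert min_bounding_rect(c) == (4, 4, 7, 7)

    def test_square_perimeter(self):
        pts = [(r, cc) for r in range(1, 4) for cc in range(1, 4) if (r, cc) != (2, 2)]
        c = Contour(points=pts, boundary_type="outer", sequence_number=2)
        assert min_bounding_rect(c) == (1, 3, 1, 3)

    def test_matches_independent_minmax_on_random_contours(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pts = [tuple(map(int, p)) for p in rng.integers(0, 50, size=(30, 2))]
            c = Contour(points=pts, boundary_type="outer", sequence_number=2)
            rows = [p[0] for p in pts]
            cols = [p[1] for p in pts]
            assert min_bounding_rect(c) == (min(rows), max(rows), min(cols), max(cols))

    def test_empty_contour_is_error(self):
        c = Contour(points=[], boundary_type="outer", sequence_number=2)
        with pytest.raises(CornoctError):
            min_bounding_rect(c)


class TestSplitEdges:
    def test_filled_rectangle_splits_into_top_and_bottom_rows(self):
        img = np.zeros((10, 12), dtype=np.uint8)
        img[3:7, 2:9] = 1
        contours = trace_boundaries(BinaryImage(img))
        c = select_corneal_contour(contours)
        upper, lower = split_edges(c, min_bounding_rect(c))
        assert np.array_equal(upper.cols, np.arange(2, 9))
        assert (upper.rows == 3).all()
        assert np.array_equal(lower.cols, np.arange(2, 9))
        assert (lower.rows == 6).all()

    def test_single_row_line_has_empty_lower_edge(self):
        img = np.zeros((5, 8), dtype=np.uint8)
        img[2, 1:7] = 1
        contours = trace_boundaries(BinaryImage(img))
        c = select_corneal_contour(contours)
        upper, lower = split_edges(c, min_bounding_rect(c))
        assert len(lower) == 0
        assert np.array_equal(upper.cols, np.arange(1, 7))
        assert (upper.rows == 2).all()

    def test_phantom_upper_edge_tracks_true_anterior_surface(self, profile, geometry):
        noise = NoiseModel(impulse_probability=0.0, speckle_scale=0.0, seed=0)
        img, _ = generate_phantom(profile, geometry, noise)
        binary = binarize(img, method="otsu", min_island_area=5)
        c = select_corneal_contour(trace_boundaries(binary))
        upper, _ = split_edges(c, min_bounding_rect(c))
        true_rows = np.asarray(evaluate_curve(geometry.upper_curve, upper.cols.astype(float)))
        frac_close = np.mean(np.abs(upper.rows - true_rows) <= 1.0)
        assert frac_close >= 0.95
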