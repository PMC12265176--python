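import numpy as np
import pytest

from aftgnet.io import ImageRecord
from aftgnet.tda import (
    PersistenceDiagram,
    ThresholdGrid,
    betti_curve,
    build_threshold_grid,
    cubical_persistence,
    extract_tda,
    sublevel_binary,
)

from conftest import flood_fill_components, flood_fill_holes

GRID5 = ThresholdGrid(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))


class TestThresholdGrid:
    def test_two_thresholds_are_range_endpoints(self):
        assert np.array_equal(build_threshold_grid(2).values, [0.0, 255.0])

    def test_default_hundred_spans_intensity_range(self):
        g = build_threshold_grid(100)
        assert len(g) == 100
        assert g.values[0] == 0.0 and g.values[-1] == 255.0
        assert np.all(np.diff(g.values) > 0)

    def test_single_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_threshold_grid(1)


class TestSublevelMasks:
    def test_inclusion_boundary_of_le_rule(self):
        img = np.full((4, 4), 40)
        assert not sublevel_binary(img, 39).any()
        assert sublevel_binary(img, 40).all()

    def test_masks_nested_over_increasing_thresholds(self, rng):
        img = rng.integers(0, 256, (16, 16))
        prev = None
        for t in (10, 30, 50, 70, 90, 255):
            mask = sublevel_binary(img, t)
            if prev is not None:
                assert np.all(prev <= mask)  # nesting
            prev = mask
        assert sublevel_binary(img, 255).all()


class TestCubicalPersistence:
    def test_constant_image_single_component_no_holes(self):
        img = np.full((5, 5), 7)
        d0 = cubical_persistence(img, dim=0)
        d1 = cubical_persistence(img, dim=1)
        assert np.array_equal(d0.points, [[7.0, np.inf]])
        assert d1.points.size == 0

    def test_bright_center_ring_creates_one_hole(self):
        img = np.ones((3, 3), dtype=int)
        img[1, 1] = 5
        d0 = cubical_persistence(img, dim=0)
        d1 = cubical_persistence(img, dim=1)
        assert np.array_equal(d0.points, [[1.0, np.inf]])
        assert np.array_equal(d1.points, [[1.0, 5.0]])

    def test_two_components_merging_records_elder_rule_pair(self):
        img = np.array([[1, 2, 1]])
        d0 = cubical_persistence(img, dim=0)
        pts = sorted(map(tuple, d0.points))
        assert pts == [(1.0, 2.0), (1.0, np.inf)]

    def test_exactly_one_essential_component(self, rng):
        img = rng.integers(0, 256, (10, 10))
        d0 = cubical_persistence(img, dim=0)
        assert np.isinf(d0.points[:, 1]).sum() == 1

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            cubical_persistence(np.zeros((2, 2, 2)), dim=0)


class TestBettiCurve:
    def test_worked_example_dimension_zero(self):
        pd0 = PersistenceDiagram(0, np.array([[1.0, np.inf], [1.0, 2.0]]))
        assert betti_curve(pd0, GRID5).counts.tolist() == [2, 1, 1, 1, 1]

    def test_worked_example_dimension_one(self):
        pd1 = PersistenceDiagram(1, np.array([[2.0, 5.0], [4.0, 5.0], [4.0, 5.0]]))
        assert betti_curve(pd1, GRID5).counts.tolist() == [0, 1, 1, 3, 0]

    def test_empty_diagram_gives_zero_curve(self):
        pd1 = PersistenceDiagram(1, np.empty((0, 2)))
        assert betti_curve(pd1, GRID5).counts.tolist() == [0] * 5


class TestOracleEquivalence:
    """Betti curves from the union-find diagrams must match flood-fill
    component and hole counts of the thresholded masks exactly."""

    def test_matches_flood_fill_on_random_images(self, rng):
        for _ in range(60):
            h, w = rng.integers(1, 13, size=2)
            img = rng.integers(0, 9, size=(int(h), int(w)))
            n_t = int(rng.integers(2, 11))
            grid = ThresholdGrid(np.linspace(0, 8, n_t))
            b0 = betti_curve(cubical_persistence(img, dim=0), grid).counts
            b1 = betti_curve(cubical_persistence(img, dim=1), grid).counts
            for i, t in enumerate(grid.values):
                mask = img <= t
                assert b0[i] == flood_fill_components(mask)
                assert b1[i] == flood_fill_holes(mask)

    def test_births_and_deaths_are_pixel_values(self, rng):
        img = rng.integers(0, 6, size=(8, 8))
        values = set(np.unique(img).tolist())
        for dim in (0, 1):
            pts = cubical_persistence(img, dim=dim).points
            finite = pts[np.isfinite(pts[:, 1])]
            assert set(pts[:, 0].tolist()) <= values
            assert set(finite[:, 1].tolist()) <= values
            assert np.all(pts[:, 0] < pts[:, 1])


class TestExtractTDA:
    def test_feature_length_is_always_800(self, random_record):
        assert extract_tda(random_record).values.shape == (800,)

    def test_constant_midgray_step_curves(self):
        rec = ImageRecord("c", np.full((64, 64, 3), 128, dtype=np.uint8))
        v = extract_tda(rec).values.reshape(4, 2, 100)
        grid = build_threshold_grid(100)
        for ch in range(4):
            expected_b0 = (grid.values >= 128).astype(int)
            assert np.array_equal(v[ch, 0], expected_b0)
            assert np.all(v[ch, 1] == 0)

    def test_final_threshold_has_single_component(self, random_record):
        v = extract_tda(random_record).values.reshape(4, 2, 100)
        assert np.all(v[:, 0, -1] == 1)
        assert np.all(v >= 0)
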