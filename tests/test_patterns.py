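"""Region detection pipeline and order-independent cluster detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from conftest import make_point_region
from stmc.errors import ParameterError
from stmc.patterns import (
    Cluster,
    ClusterDetectionConfig,
    RegionDetectionConfig,
    centroid_distance,
    detect_clusters,
    detect_regions,
    grid_to_grayscale,
)


def flood_fill_components(foreground: np.ndarray) -> list[set]:
    """Oracle: 8-connected components by explicit flood fill."""
    seen = np.zeros_like(foreground, dtype=bool)
    components = []
    rows, cols = foreground.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if foreground[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = r + dr, c + dc
                            if 0 <= nr < rows and 0 <= nc < cols \
                                    and foreground[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                stack.append((nr, nc))
                components.append(comp)
    return components


NEUTRAL = dict(alpha=1.0, beta=0.0, morph_close_iterations=0,
               blur_kernel_size=1, threshold_value=127,
               epsilon_size=0.0, approximation_level=0.0)


class TestGrayscale:
    def test_all_zero_grid_auto(self):
        assert not grid_to_grayscale(np.zeros((4, 4))).any()

    def test_max_maps_to_full_intensity(self):
        grid = np.zeros((5, 5))
        grid[2, 3] = 10.0
        assert grid_to_grayscale(grid).max() == 255

    def test_round_half_up_arithmetic(self):
        image = grid_to_grayscale([[0, 5], [10, 10]], 10)
        assert image.tolist() == [[0, 128], [255, 255]]

    def test_values_above_max_saturate(self):
        assert grid_to_grayscale([[20.0]], 10).tolist() == [[255]]

    def test_nonpositive_normalization_rejected(self):
        with pytest.raises(ParameterError):
            grid_to_grayscale([[1.0]], 0.0)


class TestDetectRegions:
    def test_all_zero_image_yields_no_regions(self):
        assert detect_regions(np.zeros((10, 10), np.uint8),
                              RegionDetectionConfig(**NEUTRAL)) == []

    def test_single_block_matches_flood_fill_oracle(self):
        image = np.zeros((20, 20), np.uint8)
        image[3:13, 4:14] = 255
        regions = detect_regions(image, RegionDetectionConfig(**NEUTRAL))
        oracle = flood_fill_components(image > 127)
        assert len(regions) == 1
        assert regions[0].holes == []
        assert set(regions[0].positions) == oracle[0]

    def test_two_blocks_and_size_filter(self):
        image = np.zeros((20, 20), np.uint8)
        image[3:13, 4:14] = 255    # 100 pixels
        image[15:19, 15:19] = 255  # 16 pixels
        assert len(detect_regions(image, RegionDetectionConfig(**NEUTRAL))) == 2
        cfg = RegionDetectionConfig(**{**NEUTRAL, "epsilon_size": 20})
        assert len(detect_regions(image, cfg)) == 1  # 16 <= 20 filtered
        cfg16 = RegionDetectionConfig(**{**NEUTRAL, "epsilon_size": 16})
        assert len(detect_regions(image, cfg16)) == 1  # strict: 16 <= 16

    def test_neutral_pipeline_equals_threshold_plus_components(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            image = (rng.random((30, 30)) < 0.35).astype(np.uint8) * 255
            regions = detect_regions(image, RegionDetectionConfig(**NEUTRAL))
            oracle = flood_fill_components(image > 127)
            assert sorted(map(sorted, (r.positions for r in regions))) \
                == sorted(map(sorted, oracle))

    def test_hole_detected(self):
        image = np.zeros((12, 12), np.uint8)
        image[2:10, 2:10] = 255
        image[4:8, 4:8] = 0  # 4x4 hole
        regions = detect_regions(image, RegionDetectionConfig(**NEUTRAL))
        assert len(regions) == 1
        assert len(regions[0].holes) == 1

    def test_even_blur_kernel_rejected(self):
        with pytest.raises(ParameterError, match="odd"):
            detect_regions(np.zeros((5, 5), np.uint8),
                           RegionDetectionConfig(**{**NEUTRAL,
                                                    "blur_kernel_size": 4}))

    def test_morphological_closing_bridges_gap(self):
        image = np.zeros((10, 20), np.uint8)
        image[4:7, 2:9] = 255
        image[4:7, 11:18] = 255  # 2-pixel gap
        assert len(detect_regions(image, RegionDetectionConfig(**NEUTRAL))) == 2
        closed = RegionDetectionConfig(**{**NEUTRAL,
                                          "morph_close_iterations": 1})
        assert len(detect_regions(image, closed)) == 1

    def test_regions_are_8_connected(self):
        rng = np.random.default_rng(11)
        image = (rng.random((25, 25)) < 0.3).astype(np.uint8) * 255
        for region in detect_regions(image, RegionDetectionConfig(**NEUTRAL)):
            mask = np.zeros((25, 25), bool)
            for r, c in region.positions:
                mask[r, c] = True
            _, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
            assert n == 1

    def test_point_mode_one_region_per_position(self):
        image = np.zeros((8, 8), np.uint8)
        image[1, 2] = 200
        image[5, 5] = 50
        cfg = RegionDetectionConfig(point_mode=True, threshold_value=50)
        regions = detect_regions(image, cfg)
        assert len(regions) == 2  # threshold is inclusive in point mode
        assert all(len(r.positions) == 1 for r in regions)
        assert {next(iter(r.positions)) for r in regions} == {(1, 2), (5, 5)}


class TestGridIO:
    def test_csv_round_trip(self, tmp_path):
        from stmc.patterns import read_grid_csv
        grid = np.array([[0.0, 1.5], [2.0, 3.25]])
        path = tmp_path / "grid.csv"
        np.savetxt(path, grid, delimiter=",")
        assert np.array_equal(read_grid_csv(path), grid)

    def test_png_grayscale(self, tmp_path):
        from PIL import Image

        from stmc.patterns import read_grid_png
        values = np.array([[0, 128], [255, 64]], dtype=np.uint8)
        path = tmp_path / "grid.png"
        Image.fromarray(values, mode="L").save(path)
        assert np.array_equal(read_grid_png(path), values.astype(float))

    def test_negative_entries_rejected(self, tmp_path):
        from stmc.errors import ParameterError
        from stmc.patterns import read_grid_csv
        path = tmp_path / "neg.csv"
        path.write_text("1,-2\n3,4\n")
        with pytest.raises(ParameterError):
            read_grid_csv(path)


class TestCentroidDistance:
    def test_three_four_five(self):
        assert centroid_distance(make_point_region(0, 0),
                                 make_point_region(3, 4)) == 5.0

    def test_identity_and_symmetry(self):
        a = make_point_region(2.5, 7.0)
        b = make_point_region(9.0, 1.0)
        assert centroid_distance(a, a) == 0.0
        assert centroid_distance(a, b) == centroid_distance(b, a)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=3))
    def test_triangle_inequality(self, points):
        a, b, c = (make_point_region(x, y) for x, y in points)
        assert centroid_distance(a, c) \
            <= centroid_distance(a, b) + centroid_distance(b, c) + 1e-9


class TestDetectClusters:
    def test_pair_at_threshold_forms_cluster(self):
        regions = [make_point_region(0, 0), make_point_region(3, 4)]
        clusters = detect_clusters(regions, ClusterDetectionConfig(
            epsilon_distance=5.0, epsilon_size=1))
        assert len(clusters) == 1
        assert len(clusters[0].members) == 2

    def test_pair_below_threshold_yields_nothing(self):
        regions = [make_point_region(0, 0), make_point_region(3, 4)]
        assert detect_clusters(regions, ClusterDetectionConfig(
            epsilon_distance=4.9, epsilon_size=1)) == []

    def test_size_filter_is_strict(self):
        regions = [make_point_region(0, 0), make_point_region(1, 0)]
        assert detect_clusters(regions, ClusterDetectionConfig(
            epsilon_distance=2.0, epsilon_size=2)) == []

    def test_permutation_invariance(self, random_region_factory):
        rng = np.random.default_rng(42)
        regions = random_region_factory(rng, 50)
        cfg = ClusterDetectionConfig(epsilon_distance=12.0, epsilon_size=1,
                                     min_neighbours=3)
        reference = detect_clusters(regions, cfg)
        ref_sets = [frozenset(m.centroid for m in c.members) for c in reference]
        for _ in range(20):
            perm = list(rng.permutation(len(regions)))
            shuffled = [regions[i] for i in perm]
            result = detect_clusters(shuffled, cfg)
            assert [frozenset(m.centroid for m in c.members)
                    for c in result] == ref_sets

    def test_output_is_partition_of_input_subset(self, random_region_factory):
        rng = np.random.default_rng(3)
        regions = random_region_factory(rng, 60)
        clusters = detect_clusters(regions, ClusterDetectionConfig(
            epsilon_distance=10.0, epsilon_size=0, min_neighbours=3))
        seen = []
        for c in clusters:
            for m in c.members:
                assert not any(m is s for s in seen)
                seen.append(m)
        all_regions = set(map(id, regions))
        assert all(id(m) in all_regions for m in seen)

    def test_border_region_goes_to_nearest_core(self):
        # two dense 6-member core columns 20 apart; the point between them
        # has too few neighbours to be core (4 + itself < 6) but is within
        # epsilon of cores on both sides, slightly closer to the left one
        left = [make_point_region(0, k) for k in range(6)]
        right = [make_point_region(20, k) for k in range(6)]
        border = make_point_region(9.9, 0)  # 9.9 from left, 10.1 from right
        cfg = ClusterDetectionConfig(epsilon_distance=10.1, epsilon_size=2,
                                     min_neighbours=6)
        clusters = detect_clusters(left + right + [border], cfg)
        assert len(clusters) == 2
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [6, 7]
        owner = [c for c in clusters
                 if any(m.centroid == (9.9, 0.0) for m in c.members)]
        assert len(owner) == 1
        assert any(m.centroid == (0.0, 0.0) for m in owner[0].members)

    def test_empty_input(self):
        assert detect_clusters([], ClusterDetectionConfig()) == []

    def test_cluster_centroid_is_hull_centroid(self):
        cluster = Cluster(members=[make_point_region(0, 0),
                                   make_point_region(4, 0),
                                   make_point_region(0, 4),
                                   make_point_region(4, 4)])
        assert cluster.centroid == (2.0, 2.0)
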