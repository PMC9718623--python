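"""Superpixel graph construction, manifold ranking and saliency stages."""

import numpy as np
import pytest

from grainsight import segmentation as seg
from grainsight.segmentation import (
    AffinityMatrix,
    background_saliency,
    build_affinity,
    build_superpixel_graph,
    combine_and_refine,
    compactness_saliency,
    manifold_rank,
    minmax_norm,
    saliency_to_mask,
    segment_image,
)


def brute_force_rank(weights: np.ndarray, seeds: np.ndarray, alpha: float) -> np.ndarray:
    """Independent oracle: explicit resolvent inverse, elementwise loops."""
    n = weights.shape[0]
    P = np.zeros((n, n))
    for i in range(n):
        deg = weights[i].sum()
        if deg > 0:
            for j in range(n):
                P[i, j] = weights[i, j] / deg
    return np.linalg.inv(np.eye(n) - alpha * P) @ seeds


def random_graph(rng, n):
    upper = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.4), k=1)
    return upper + upper.T


class TestManifoldRank:
    def test_matches_dense_brute_force_on_small_graphs(self, rng):
        for n in range(2, 21):
            W = random_graph(rng, n)
            seeds = rng.random(n)
            got = manifold_rank(W, seeds, alpha=0.85)
            np.testing.assert_allclose(got, brute_force_rank(W, seeds, 0.85), atol=1e-8)

    def test_alpha_zero_returns_seeds(self, rng):
        W = random_graph(rng, 8)
        seeds = rng.random(8)
        np.testing.assert_allclose(manifold_rank(W, seeds, alpha=0.0), seeds)

    def test_two_node_closed_form(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        got = manifold_rank(W, np.array([1.0, 0.0]), alpha=0.5)
        np.testing.assert_allclose(got, [4 / 3, 2 / 3])

    def test_vertex_transitive_uniform_seeds_stay_uniform(self):
        n = 6  # cycle graph
        W = np.zeros((n, n))
        for i in range(n):
            W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
        out = manifold_rank(W, np.ones(n), alpha=0.9)
        np.testing.assert_allclose(out, out[0])

    def test_monotone_in_seeds(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 12))
            W = random_graph(rng, n)
            seeds = rng.random(n)
            base = manifold_rank(W, seeds, alpha=0.8)
            bumped = seeds.copy()
            k = int(rng.integers(n))
            bumped[k] += 0.5
            out = manifold_rank(W, bumped, alpha=0.8)
            assert np.all(out >= base - 1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            manifold_rank(np.eye(2) * 0, np.ones(2), alpha=1.0)


class TestSuperpixelGraph:
    def test_uniform_image_constant_lab_and_centered(self):
        image = np.full((96, 96, 3), 128, dtype=np.uint8)
        graph = build_superpixel_graph(image, n_segments=64)
        graph.validate()
        assert np.ptp(graph.mean_lab, axis=0).max() < 1e-4
        np.testing.assert_allclose(graph.centroid.mean(axis=0), [0.5, 0.5], atol=0.05)

    def test_node_count_in_oversegmentation_band(self, grain_samples):
        graph = build_superpixel_graph(grain_samples[0].image, n_segments=100)
        assert 50 <= graph.n_nodes <= 150

    def test_rejects_more_segments_than_pixels(self):
        image = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            build_superpixel_graph(image, n_segments=100)


class TestAffinity:
    def test_kernel_values(self, grain_samples):
        graph = build_superpixel_graph(grain_samples[0].image, n_segments=60)
        W = build_affinity(graph, sigma_c=10.0)
        assert np.allclose(W.weights, W.weights.T)
        assert np.all(np.diag(W.weights) == 0)
        assert W.weights.max() <= 1.0 and W.weights.min() >= 0.0

    def test_identical_colors_adjacent_weight_one(self):
        graph = _toy_graph(colors=np.zeros((4, 3)))
        W = build_affinity(graph, sigma_c=5.0)
        i, j = next(iter(graph.adjacency))
        assert W.weights[i, j] == pytest.approx(1.0)

    def test_distance_equals_bandwidth_gives_e_minus_one(self):
        colors = np.zeros((4, 3))
        colors[1, 0] = 7.0
        graph = _toy_graph(colors=colors)
        W = build_affinity(graph, sigma_c=7.0)
        assert W.weights[0, 1] == pytest.approx(np.exp(-1.0))

    def test_nonpositive_bandwidth_rejected(self, grain_samples):
        graph = build_superpixel_graph(grain_samples[0].image, n_segments=60)
        with pytest.raises(ValueError):
            build_affinity(graph, sigma_c=0.0)


def _toy_graph(colors: np.ndarray) -> seg.SuperpixelGraph:
    """A 2x2-node toy graph over a 4x4 image, fully specified by hand."""
    label_map = np.repeat(np.repeat(np.arange(4).reshape(2, 2), 2, axis=0), 2, axis=1)
    return seg.SuperpixelGraph(
        label_map=label_map,
        n_nodes=4,
        mean_lab=colors,
        centroid=np.array([[0.25, 0.25], [0.25, 0.75], [0.75, 0.25], [0.75, 0.75]]),
        adjacency={(0, 1), (1, 0), (0, 2), (2, 0), (1, 3), (3, 1), (2, 3), (3, 2)},
        boundary={"top": {0, 1}, "left": {0, 2}, "right": {1, 3}},
    )


class TestBackgroundSaliency:
    def test_extremes_after_complement(self, grain_samples):
        graph = build_superpixel_graph(grain_samples[0].image, n_segments=80)
        W = build_affinity(graph)
        I_b = background_saliency(graph, W)
        assert I_b.values.min() == pytest.approx(0.0)
        assert I_b.values.max() == pytest.approx(1.0)

    def test_distinct_center_node_attains_max(self):
        # 3x3 superpixel toy: center color far from the eight border nodes
        label_map = np.repeat(np.repeat(np.arange(9).reshape(3, 3), 3, axis=0), 3, axis=1)
        colors = np.zeros((9, 3))
        colors[4] = [60.0, 0.0, 0.0]
        rows, cols = np.divmod(np.arange(9), 3)
        centroid = np.stack([rows, cols], axis=1) / 2.0
        adjacency = set()
        for i in range(9):
            for j in range(9):
                if i != j and abs(rows[i] - rows[j]) + abs(cols[i] - cols[j]) == 1:
                    adjacency.add((i, j))
        graph = seg.SuperpixelGraph(
            label_map=label_map, n_nodes=9, mean_lab=colors, centroid=centroid,
            adjacency=adjacency,
            boundary={"top": {0, 1, 2}, "left": {0, 3, 6}, "right": {2, 5, 8}},
        )
        W = build_affinity(graph, sigma_c=10.0)
        I_b = background_saliency(graph, W)
        # oracle: recompute the staged formula with the brute-force solver
        product = np.ones(9)
        for side in ("top", "left", "right"):
            y = np.zeros(9)
            y[list(graph.boundary[side])] = 1.0
            product *= brute_force_rank(W.weights, y, 0.99)
        expected = 1.0 - (product - product.min()) / np.ptp(product)
        np.testing.assert_allclose(I_b.values, expected, atol=1e-8)
        # the distinct center outranks every seeded border node; only the
        # unseeded bottom-middle node may tie with it
        seeded = sorted(set().union(*graph.boundary.values()))
        assert I_b.values[4] > I_b.values[seeded].max()
        assert 4 in np.argsort(I_b.values)[-2:]

    def test_empty_boundary_rejected(self):
        graph = _toy_graph(colors=np.zeros((4, 3)))
        graph.boundary["top"] = set()
        with pytest.raises(ValueError):
            background_saliency(graph, build_affinity(graph))


class TestCompactness:
    def test_single_node_graph_returns_one(self):
        graph = seg.SuperpixelGraph(
            label_map=np.zeros((2, 2), dtype=int), n_nodes=1,
            mean_lab=np.zeros((1, 3)), centroid=np.array([[0.5, 0.5]]),
            adjacency=set(), boundary={"top": {0}, "left": {0}, "right": {0}},
        )
        W = AffinityMatrix(stage="J1", weights=np.zeros((1, 1)), sigma_c=10.0)
        out = compactness_saliency(graph, W, np.ones(1))
        np.testing.assert_allclose(out.values, [1.0])

    def test_tight_bright_cluster_scores_higher(self):
        # tight, strongly connected cluster near the weighted center vs
        # dispersed dim nodes
        n = 8
        centroid = np.array(
            [[0.48, 0.48], [0.52, 0.48], [0.48, 0.52], [0.52, 0.52],
             [0.05, 0.05], [0.05, 0.95], [0.95, 0.05], [0.95, 0.95]]
        )
        weights = np.zeros((n, n))
        for i in range(4):
            for j in range(4):
                if i != j:
                    weights[i, j] = 1.0
        for i in range(n):
            for j in range(n):
                if i != j and weights[i, j] == 0:
                    weights[i, j] = 0.05
        graph = seg.SuperpixelGraph(
            label_map=np.zeros((4, 4), dtype=int), n_nodes=n,
            mean_lab=np.zeros((n, 3)), centroid=centroid, adjacency=set(),
            boundary={"top": {4}, "left": {5}, "right": {6}},
        )
        W = AffinityMatrix(stage="J1", weights=weights, sigma_c=10.0)
        scores = np.array([1.0] * 4 + [0.1] * 4)
        I_f = compactness_saliency(graph, W, scores)
        assert I_f.values[:4].mean() > I_f.values[4:].mean()


class TestCombineAndRefine:
    def test_constant_stages_give_constant_refinement(self, grain_samples):
        graph = build_superpixel_graph(grain_samples[0].image, n_segments=60)
        W = build_affinity(graph)
        const = seg.SaliencyVector(values=np.full(graph.n_nodes, 0.5), kind="I_b")
        I_2 = combine_and_refine(const, const, graph, W)
        assert np.ptp(I_2.values) == pytest.approx(0.0)

    def test_large_sigma_s_with_vanishing_color_weights_matches_unweighted(self, grain_samples):
        graph = build_superpixel_graph(grain_samples[0].image, n_segments=60)
        W = build_affinity(graph)
        tiny = AffinityMatrix(stage="J1", weights=W.weights * 1e-12, sigma_c=W.sigma_c)
        rng = np.random.default_rng(3)
        I_b = seg.SaliencyVector(values=rng.random(graph.n_nodes), kind="I_b")
        I_f = seg.SaliencyVector(values=rng.random(graph.n_nodes), kind="I_f")
        I_2 = combine_and_refine(I_b, I_f, graph, tiny, sigma_s=1e12)
        I_1 = minmax_norm(I_b.values + I_f.values)
        unweighted = (W.weights > 0).astype(float)
        expected = minmax_norm(manifold_rank(unweighted, I_1, 0.99))
        np.testing.assert_allclose(I_2.values, expected, atol=1e-6)

    def test_grain_nodes_outscore_background(self, grain_samples):
        sample = grain_samples[4]
        graph = build_superpixel_graph(sample.image, n_segments=200)
        W = build_affinity(graph)
        I_b = background_saliency(graph, W)
        I_f = compactness_saliency(graph, W, I_b.values)
        I_2 = combine_and_refine(I_b, I_f, graph, W)
        flat = graph.label_map.ravel()
        frac = np.bincount(flat, weights=sample.mask.ravel().astype(float),
                           minlength=graph.n_nodes)
        frac /= np.bincount(flat, minlength=graph.n_nodes)
        grain = frac > 0.5
        assert I_2.values[grain].mean() > I_2.values[~grain].mean()


class TestSaliencyToMask:
    def test_binary_raster_recovered_exactly(self):
        label_map = np.repeat(np.repeat(np.arange(4).reshape(2, 2), 4, axis=0), 4, axis=1)
        graph = _toy_graph(colors=np.zeros((4, 3)))
        graph.label_map = label_map
        values = np.array([0.0, 1.0, 0.0, 1.0])
        image = np.zeros((8, 8, 3), dtype=np.uint8)
        res = saliency_to_mask(values, graph, image)
        np.testing.assert_array_equal(res.mask, (values[label_map] == 1.0).astype(np.uint8))

    def test_mask_counts_match_threshold_rule(self, grain_samples):
        res = segment_image(grain_samples[3].image)
        assert res.mask.sum() == (res.saliency_raster >= res.threshold).sum()

    def test_constant_saliency_yields_empty_mask(self):
        graph = _toy_graph(colors=np.zeros((4, 3)))
        image = np.zeros((4, 4, 3), dtype=np.uint8)
        res = saliency_to_mask(np.full(4, 0.7), graph, image)
        assert res.mask.sum() == 0

    def test_colormapped_background_is_constant(self, grain_samples):
        res = segment_image(grain_samples[2].image)
        outside = res.colormapped[~res.mask.astype(bool)]
        assert np.all(outside == 0.0)


class TestSaliencyRange:
    def test_all_stage_outputs_in_unit_interval(self, grain_samples):
        graph = build_superpixel_graph(grain_samples[1].image, n_segments=120)
        W = build_affinity(graph)
        I_b = background_saliency(graph, W)
        I_f = compactness_saliency(graph, W, I_b.values)
        I_2 = combine_and_refine(I_b, I_f, graph, W)
        for vec in (I_b, I_f, I_2):
            assert vec.values.min() >= 0.0 and vec.values.max() <= 1.0
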