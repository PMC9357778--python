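"""Unit tests for the histogram-domain robust FCM segmenter, each checked
against an independent brute-force oracle where one exists."""

import itertools

import numpy as np
import pytest

from neuroseg import ifrfcm, metrics, synthetic
from neuroseg.ifrfcm import ClusterConfig


# ---------------------------------------------------------------- oracles

def geodesic_reconstruct_oracle(marker, mask, method):
    """Iterated geodesic dilation (or erosion) to stability, 8-connected."""
    cur = marker.astype(float).copy()
    mask = mask.astype(float)
    while True:
        if method == "dilation":
            grown = np.pad(cur, 1, constant_values=-np.inf)
            nxt = cur.copy()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nxt = np.maximum(
                        nxt, grown[1 + dr:grown.shape[0] - 1 + dr,
                                   1 + dc:grown.shape[1] - 1 + dc])
            nxt = np.minimum(nxt, mask)
        else:
            grown = np.pad(cur, 1, constant_values=np.inf)
            nxt = cur.copy()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nxt = np.minimum(
                        nxt, grown[1 + dr:grown.shape[0] - 1 + dr,
                                   1 + dc:grown.shape[1] - 1 + dc])
            nxt = np.maximum(nxt, mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def fuzzy_factor_oracle(S, centroids, image, config, pixel, cluster):
    """Explicit loop over the neighborhood."""
    total = 0.0
    radius = config.neighborhood_radius
    row, col = pixel
    for r in range(row - radius, row + radius + 1):
        for c in range(col - radius, col + radius + 1):
            if (r, c) == (row, col):
                continue
            if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
                continue
            d = np.hypot(r - row, c - col)
            s = S[cluster, int(image[r, c])]
            total += (1 - s) ** config.fuzziness \
                * (float(image[r, c]) - centroids[cluster]) ** 2 / (d + 1)
    return config.alpha * total


def wiener_oracle(plane, window):
    """Naive sliding-window local-statistics Wiener filter (edge-mirrored
    padding, matching scipy.ndimage's 'reflect')."""
    r = window // 2
    padded = np.pad(plane, r, mode="symmetric")
    means = np.zeros_like(plane, dtype=float)
    varis = np.zeros_like(plane, dtype=float)
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            win = padded[i:i + window, j:j + window]
            means[i, j] = win.mean()
            varis[i, j] = win.var()
    noise = varis.mean()
    out = means.copy()
    strong = varis > noise
    out[strong] = means[strong] + (1 - noise / varis[strong]) \
        * (plane[strong] - means[strong])
    return out


def plain_fcm_config(seed, **kw):
    return ClusterConfig(n_clusters=3, seed=seed, use_reconstruction=False,
                         use_wiener=False, neighborhood_radius=0, **kw)


# ------------------------------------------------- morphological_reconstruct

class TestMorphologicalReconstruct:
    def test_flat_image_unchanged(self):
        img = np.full((9, 9), 7, dtype=np.int64)
        assert np.array_equal(ifrfcm.morphological_reconstruct(img, 1), img)

    def test_impulse_removed_matches_oracle(self):
        img = np.full((9, 9), 10, dtype=np.int64)
        img[4, 4] = 250
        out = ifrfcm.morphological_reconstruct(img, 1)
        assert out[4, 4] == 10
        # brute-force: opening-by-reconstruction then closing-by-recon
        from skimage.morphology import disk, erosion, dilation
        opened = geodesic_reconstruct_oracle(
            erosion(img, disk(1)), img, "dilation")
        closed = geodesic_reconstruct_oracle(
            dilation(opened, disk(1)), opened, "erosion")
        assert np.array_equal(out, closed.astype(np.int64))

    def test_idempotent(self, noisy_phantom):
        once = ifrfcm.morphological_reconstruct(noisy_phantom.image, 1)
        twice = ifrfcm.morphological_reconstruct(once, 1)
        assert np.array_equal(once, twice)

    def test_value_range_preserved(self, noisy_phantom):
        out = ifrfcm.morphological_reconstruct(noisy_phantom.image, 1)
        assert out.min() >= noisy_phantom.image.min()
        assert out.max() <= noisy_phantom.image.max()

    def test_radius_too_large(self):
        with pytest.raises(ValueError):
            ifrfcm.morphological_reconstruct(np.zeros((8, 8), int), 5)


# ---------------------------------------------------- compute_gray_histogram

class TestGrayHistogram:
    def test_constant_image(self):
        img = np.full((4, 4), 5, dtype=np.int64)
        counts = ifrfcm.compute_gray_histogram(img, 256)
        assert counts[5] == 16
        assert counts.sum() == 16
        assert np.count_nonzero(counts) == 1

    def test_conservation(self, noisy_phantom):
        counts = ifrfcm.compute_gray_histogram(noisy_phantom.image, 256)
        assert counts.sum() == noisy_phantom.image.size

    def test_matches_naive_tally(self, rng):
        img = rng.integers(0, 8, size=(8, 8))
        counts = ifrfcm.compute_gray_histogram(img, 8)
        naive = [int(np.sum(img == z)) for z in range(8)]
        assert counts.tolist() == naive

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ifrfcm.compute_gray_histogram(np.full((2, 2), 9), levels=8)


# ------------------------------------------------------------- fuzzy_factor

class TestFuzzyFactor:
    def setup_method(self):
        self.config = ClusterConfig(n_clusters=2, neighborhood_radius=1)

    def test_full_membership_gives_zero(self):
        img = np.arange(9).reshape(3, 3)
        S = np.ones((2, 9))
        assert ifrfcm.fuzzy_factor(
            S, np.array([4.0, 5.0]), img, self.config, (1, 1), 0) == 0.0

    def test_values_at_centroid_give_zero(self):
        img = np.full((3, 3), 4, dtype=np.int64)
        S = np.zeros((2, 9))
        assert ifrfcm.fuzzy_factor(
            S, np.array([4.0, 7.0]), img, self.config, (1, 1), 0) == 0.0

    def test_zero_radius(self):
        img = np.arange(9).reshape(3, 3)
        config = ClusterConfig(n_clusters=2, neighborhood_radius=0)
        S = np.zeros((2, 9))
        assert ifrfcm.fuzzy_factor(
            S, np.array([1.0, 2.0]), img, config, (1, 1), 1) == 0.0

    def test_matches_loop_oracle(self, rng):
        img = rng.integers(0, 16, size=(5, 5))
        S = rng.random((2, 16))
        centroids = np.array([3.0, 12.0])
        for pixel in [(0, 0), (2, 2), (4, 1)]:
            for q in (0, 1):
                got = ifrfcm.fuzzy_factor(
                    S, centroids, img, self.config, pixel, q)
                want = fuzzy_factor_oracle(
                    S, centroids, img, self.config, pixel, q)
                assert got == pytest.approx(want, rel=1e-12)

    def test_field_matches_pointwise(self, rng):
        img = rng.integers(0, 16, size=(6, 7))
        S = rng.random((3, 16))
        centroids = np.array([2.0, 8.0, 14.0])
        config = ClusterConfig(n_clusters=3, neighborhood_radius=2)
        field = ifrfcm.fuzzy_factor_field(S, centroids, img, config)
        for q in range(3):
            for i in range(6):
                for j in range(7):
                    want = ifrfcm.fuzzy_factor(
                        S, centroids, img, config, (i, j), q)
                    assert field[q, i, j] == pytest.approx(want, abs=1e-9)


# ------------------------------------------------- membership and centroids

class TestUpdates:
    def test_single_cluster_membership_one(self):
        S = ifrfcm.update_memberships(np.array([5.0]), np.arange(10.0), 2.0)
        assert np.all(S == 1.0)

    def test_midpoint_split(self):
        S = ifrfcm.update_memberships(
            np.array([0.0, 10.0]), np.array([5.0]), 2.0)
        assert S[:, 0] == pytest.approx([0.5, 0.5])

    def test_zero_distance_tie_split(self):
        S = ifrfcm.update_memberships(
            np.array([3.0, 3.0, 8.0]), np.array([3.0, 8.0]), 2.0)
        assert S[:, 0] == pytest.approx([0.5, 0.5, 0.0])
        assert S[:, 1] == pytest.approx([0.0, 0.0, 1.0])

    def test_columns_sum_to_one(self, rng):
        S = ifrfcm.update_memberships(
            rng.uniform(0, 255, 4), np.arange(256.0), 1.7,
            rng.uniform(0, 10, (4, 256)))
        assert np.allclose(S.sum(axis=0), 1.0, atol=1e-9)

    def test_membership_matches_simplex_grid_oracle(self):
        # 3 gray levels, C=2, v=2, G=0: the analytic update must match a
        # grid search of the objective over the membership simplex
        xi = np.array([0.0, 4.0, 9.0])
        counts = np.array([3.0, 1.0, 2.0])
        centroids = np.array([1.0, 7.0])
        S = ifrfcm.update_memberships(centroids, xi, 2.0)
        grid = np.linspace(0, 1, 2001)
        for z in range(3):
            costs = counts[z] * (
                grid ** 2 * (xi[z] - centroids[0]) ** 2
                + (1 - grid) ** 2 * (xi[z] - centroids[1]) ** 2)
            assert S[0, z] == pytest.approx(grid[np.argmin(costs)], abs=1e-3)

    def test_centroid_full_membership_weighted_mean(self):
        counts = np.array([2.0, 0.0, 6.0])
        xi = np.array([0.0, 1.0, 2.0])
        c = ifrfcm.update_centroids(np.ones((1, 3)), counts, xi, 2.0)
        assert c[0] == pytest.approx((0 * 2 + 2 * 6) / 8)

    def test_centroid_symmetry(self):
        counts = np.array([5.0, 5.0])
        xi = np.array([10.0, 20.0])
        S = np.array([[0.7, 0.7]])
        c = ifrfcm.update_centroids(S, counts, xi, 2.0)
        assert c[0] == pytest.approx(15.0)

    def test_centroid_matches_loop_oracle(self, rng):
        counts = rng.integers(0, 10, 12).astype(float)
        counts[0] = 1  # ensure mass
        xi = np.arange(12.0)
        S = rng.random((3, 12))
        v = 2.3
        got = ifrfcm.update_centroids(S, counts, xi, v)
        for q in range(3):
            num = sum(counts[z] * S[q, z] ** v * xi[z] for z in range(12))
            den = sum(counts[z] * S[q, z] ** v for z in range(12))
            assert got[q] == pytest.approx(num / den, rel=1e-12)

    def test_starved_cluster_reseeded(self):
        counts = np.array([1.0, 0.0, 9.0])
        xi = np.arange(3.0)
        S = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning):
            c = ifrfcm.update_centroids(S, counts, xi, 2.0)
        assert c[1] == 2.0  # modal gray level


# ---------------------------------------------------------------- objective

class TestObjective:
    def test_perfect_fit_zero(self):
        xi = np.array([1.0, 5.0])
        counts = np.array([3.0, 4.0])
        S = np.eye(2)
        j = ifrfcm.objective(S, np.array([1.0, 5.0]), counts, xi, 2.0)
        assert j == 0.0

    def test_hand_example(self):
        xi = np.array([0.0, 1.0, 2.0])
        counts = np.array([1.0, 2.0, 3.0])
        S = np.array([[1.0, 0.5, 0.0], [0.0, 0.5, 1.0]])
        centroids = np.array([0.0, 2.0])
        gbar = np.full((2, 3), 0.25)
        want = 0.0
        for q in range(2):
            for z in range(3):
                want += counts[z] * S[q, z] ** 2 * (xi[z] - centroids[q]) ** 2
                want += gbar[q, z]
        got = ifrfcm.objective(S, centroids, counts, xi, 2.0, gbar)
        assert got == pytest.approx(want, rel=1e-12)

    def test_plain_fcm_descent(self, noisy_phantom):
        res = ifrfcm.segment(noisy_phantom.image, plain_fcm_config(3))
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8 * np.abs(trace[:-1]) + 1e-9)


# --------------------------------------------------- wiener_filter_membership

class TestWienerFilter:
    def test_constant_plane_unchanged(self):
        img = np.zeros((8, 8), dtype=np.int64)
        S = np.array([[0.3], [0.7]])
        out = ifrfcm.wiener_filter_membership(S, img, 3)
        assert np.allclose(out[0], 0.3) and np.allclose(out[1], 0.7)

    def test_per_pixel_normalization(self, rng):
        img = rng.integers(0, 16, size=(12, 12))
        S = rng.random((3, 16))
        S /= S.sum(axis=0)
        out = ifrfcm.wiener_filter_membership(S, img, 5)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-9)

    def test_impulse_matches_naive_oracle(self):
        img = np.zeros((7, 7), dtype=np.int64)
        img[3, 3] = 1
        S = np.array([[1.0, 0.0]])  # plane = 1 everywhere except impulse 0
        plane = S[0, img]
        want = wiener_oracle(plane.astype(float), 3)
        got = ifrfcm._adaptive_wiener(plane.astype(float), 3)
        assert np.allclose(got, want, atol=1e-12)

    def test_oracle_on_random_plane(self, rng):
        plane = rng.random((9, 10))
        assert np.allclose(ifrfcm._adaptive_wiener(plane, 3),
                           wiener_oracle(plane, 3), atol=1e-10)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            ifrfcm.wiener_filter_membership(
                np.ones((1, 4)), np.zeros((3, 3), int), 5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ifrfcm.wiener_filter_membership(
                np.ones((1, 4)), np.zeros((8, 8), int), 4)


# ------------------------------------------------------------------ segment

class TestSegment:
    def test_noiseless_two_level_exact(self):
        img = np.full((40, 40), 30, dtype=np.int64)
        img[10:30, 10:30] = 200
        res = ifrfcm.segment(img, ClusterConfig(n_clusters=2, seed=0))
        truth = (img == 200).astype(int)
        assert metrics.permutation_matched_accuracy(res.labels, truth) == 1.0

    def test_beats_plain_fcm_on_noise(self):
        ph = synthetic.generate_phantom(
            size=64, tumor=False, noise_kind="salt_pepper",
            noise_level=0.05, seed=3)
        full = ifrfcm.segment(ph.image, ClusterConfig(n_clusters=3, seed=3))
        plain = ifrfcm.segment(ph.image, plain_fcm_config(3))
        acc_full = metrics.permutation_matched_accuracy(full.labels, ph.truth)
        acc_plain = metrics.permutation_matched_accuracy(plain.labels, ph.truth)
        assert acc_full > acc_plain

    def test_permutation_invariant_scoring(self, rng):
        labels = rng.integers(0, 3, size=(20, 20))
        truth = rng.integers(0, 3, size=(20, 20))
        base = metrics.permutation_matched_accuracy(labels, truth)
        perm = np.array([2, 0, 1])
        assert metrics.permutation_matched_accuracy(
            perm[labels], truth) == pytest.approx(base)

    def test_deterministic(self, noisy_phantom):
        r1 = ifrfcm.segment(noisy_phantom.image,
                            ClusterConfig(n_clusters=3, seed=11))
        r2 = ifrfcm.segment(noisy_phantom.image,
                            ClusterConfig(n_clusters=3, seed=11))
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.centroids, r2.centroids)

    def test_nonconvergence_flagged_not_raised(self, noisy_phantom):
        res = ifrfcm.segment(
            noisy_phantom.image,
            ClusterConfig(n_clusters=3, seed=0, max_iter=2, tol=1e-12))
        assert not res.converged
        assert res.n_iter == 2
        assert len(res.objective_trace) == 2

    def test_labels_in_range_and_trace_length(self, noisy_phantom):
        res = ifrfcm.segment(noisy_phantom.image,
                             ClusterConfig(n_clusters=3, seed=0))
        assert res.labels.min() >= 0 and res.labels.max() <= 2
        assert len(res.objective_trace) == res.n_iter

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ClusterConfig(fuzziness=1.0).validate()
        with pytest.raises(ValueError):
            ClusterConfig(wiener_window=4).validate()


# --------------------------------------------------- histogram/pixel parity

def pixel_domain_fcm(image, centroids, v, n_iter):
    """Brute-force FCM over individual pixels (the slow classical route)."""
    x = image.ravel().astype(float)
    c = np.asarray(centroids, dtype=float).copy()
    for _ in range(n_iter):
        d = np.maximum((x[None, :] - c[:, None]) ** 2, 1e-300)
        inv = d ** (-1.0 / (v - 1.0))
        S = inv / inv.sum(axis=0)
        c = (S ** v @ x) / (S ** v).sum(axis=1)
    return c


def test_histogram_equals_pixel_domain_fcm(rng):
    ph = synthetic.generate_phantom(
        size=64, tumor=True, noise_kind="gaussian", noise_level=0.03, seed=9)
    counts = ifrfcm.compute_gray_histogram(ph.image, 256).astype(float)
    xi = np.arange(256.0)
    c = ifrfcm._init_centroids(counts, 3, np.random.default_rng(2))
    c0 = c.copy()
    for _ in range(50):
        S = ifrfcm.update_memberships(c, xi, 2.0)
        c = ifrfcm.update_centroids(S, counts, xi, 2.0)
    cp = pixel_domain_fcm(ph.image, c0, 2.0, 50)
    assert np.max(np.abs(c - cp)) < 1e-6
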