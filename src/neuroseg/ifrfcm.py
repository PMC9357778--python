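"""Noise-robust fuzzy C-means segmentation over the gray-level histogram.

The segmenter runs four stages:

1. morphological reconstruction (opening- then closing-by-reconstruction)
   to suppress impulse noise while preserving edges,
2. fuzzy C-means clustering of the gray-level *histogram* (clusters x
   gray-levels membership matrix, which is much cheaper than clustering
   every pixel) with an optional spatial "fuzzy factor" penalty that pulls
   a pixel's membership toward its neighbors',
3. an adaptive Wiener filter on the pixel-domain membership planes,
4. defuzzification by per-pixel argmax.

Disabling reconstruction, the fuzzy factor (``neighborhood_radius=0``) and
the Wiener stage recovers plain histogram FCM, which is used as the
comparison baseline in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, erosion, dilation, reconstruction

__all__ = [
    "ClusterConfig",
    "SegmentationResult",
    "morphological_reconstruct",
    "compute_gray_histogram",
    "fuzzy_factor",
    "fuzzy_factor_field",
    "aggregate_fuzzy_factor",
    "update_memberships",
    "update_centroids",
    "objective",
    "wiener_filter_membership",
    "expand_memberships",
    "segment",
]


@dataclass
class ClusterConfig:
    """Parameters of the histogram-domain fuzzy clustering.

    ``fuzziness`` is the membership exponent (> 1); ``alpha`` scales the
    spatial fuzzy factor; ``neighborhood_radius`` is the half-width of the
    square neighborhood used by the fuzzy factor (0 disables it).
    """

    n_clusters: int = 3
    fuzziness: float = 2.0
    alpha: float = 1.0
    neighborhood_radius: int = 1
    reconstruction_radius: int = 1
    use_reconstruction: bool = True
    use_wiener: bool = True
    wiener_window: int = 3
    max_iter: int = 100
    tol: float = 1e-4
    levels: int = 256
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.fuzziness <= 1.0:
            raise ValueError("fuzziness must be > 1 (update undefined at 1)")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.neighborhood_radius < 0:
            raise ValueError("neighborhood_radius must be >= 0")
        if self.wiener_window < 3 or self.wiener_window % 2 == 0:
            raise ValueError("wiener_window must be odd and >= 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass
class SegmentationResult:
    labels: np.ndarray                 # (H, W) cluster indices
    memberships: np.ndarray            # (C, H, W) filtered pixel memberships
    memberships_gray: np.ndarray       # (C, h) histogram-domain memberships
    centroids: np.ndarray              # (C,) gray-value cluster centers
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    if np.any(image < 0):
        raise ValueError("gray values must be non-negative")
    return image


def morphological_reconstruct(image: np.ndarray, radius: int = 1) -> np.ndarray:
    """Opening-by-reconstruction followed by closing-by-reconstruction.

    Removes bright and dark structures smaller than the disk structuring
    element while leaving larger regions and their edges untouched.  The
    operator is idempotent: applying it to its own output is a no-op.
    """
    image = _check_image(image)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > min(image.shape) / 2:
        raise ValueError(
            f"radius {radius} too large for image of shape {image.shape}"
        )
    selem = disk(radius)
    # opening by reconstruction: erode, then geodesic dilation under the image
    opened = reconstruction(erosion(image, selem), image, method="dilation")
    # closing by reconstruction: dilate, then geodesic erosion above the image
    closed = reconstruction(dilation(opened, selem), opened, method="erosion")
    out = np.rint(closed).astype(image.dtype) if np.issubdtype(
        image.dtype, np.integer) else closed
    return out


def compute_gray_histogram(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Per-gray-level pixel counts; ``counts.sum()`` equals the pixel count."""
    image = _check_image(image)
    vals = np.rint(image).astype(np.int64)
    if vals.max() >= levels:
        raise ValueError(
            f"gray value {vals.max()} outside [0, {levels - 1}]"
        )
    return np.bincount(vals.ravel(), minlength=levels)


def _neighbor_kernel(radius: int) -> np.ndarray:
    """Inverse-distance weights 1/(d+1) on a (2r+1)^2 window, center zeroed."""
    size = 2 * radius + 1
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    d = np.hypot(dy, dx)
    kernel = 1.0 / (d + 1.0)
    kernel[radius, radius] = 0.0
    return kernel


def fuzzy_factor(
    memberships: np.ndarray,
    centroids: np.ndarray,
    image: np.ndarray,
    config: ClusterConfig,
    pixel: tuple[int, int],
    cluster: int,
) -> float:
    """Spatial penalty G for one pixel/cluster pair.

    G = alpha * sum over neighbors r of 1/(d_pr + 1) * (1 - s_qr)^v
    * (x_r - p_q)^2 where s_qr is the neighbor's membership in cluster q
    (looked up through its gray value) and d_pr the Euclidean pixel
    distance.  Returns 0 when the neighborhood radius is 0.
    """
    image = _check_image(image)
    row, col = pixel
    if not (0 <= row < image.shape[0] and 0 <= col < image.shape[1]):
        raise ValueError("pixel outside image")
    if cluster >= memberships.shape[0]:
        raise ValueError("cluster index out of range")
    radius = config.neighborhood_radius
    if radius == 0:
        return 0.0
    v = config.fuzziness
    total = 0.0
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr == 0 and dc == 0:
                continue
            r, c = row + dr, col + dc
            if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
                continue
            d = float(np.hypot(dr, dc))
            s = memberships[cluster, int(image[r, c])]
            total += (1.0 - s) ** v * (float(image[r, c]) -
                                       float(centroids[cluster])) ** 2 / (d + 1.0)
    return config.alpha * total


def fuzzy_factor_field(
    memberships: np.ndarray,
    centroids: np.ndarray,
    image: np.ndarray,
    config: ClusterConfig,
) -> np.ndarray:
    """Vectorized per-pixel fuzzy factor, shape (C, H, W).

    Equivalent to calling :func:`fuzzy_factor` at every pixel: the penalty
    is a sum of per-neighbor terms, so it is a convolution of the
    per-pixel quantity (1 - s_q)^v * (x - p_q)^2 with the inverse-distance
    kernel (zero padding drops out-of-image neighbors).
    """
    radius = config.neighborhood_radius
    C = memberships.shape[0]
    if radius == 0:
        return np.zeros((C,) + image.shape)
    kernel = _neighbor_kernel(radius)
    gray = np.rint(image).astype(np.int64)
    x = gray.astype(float)
    out = np.empty((C,) + image.shape)
    for q in range(C):
        b = (1.0 - memberships[q, gray]) ** config.fuzziness \
            * (x - centroids[q]) ** 2
        out[q] = ndimage.convolve(b, kernel, mode="constant", cval=0.0)
    return config.alpha * out


def aggregate_fuzzy_factor(
    factor_field: np.ndarray, image: np.ndarray, levels: int
) -> np.ndarray:
    """Average the pixel-domain fuzzy factor over pixels of each gray level.

    Produces the (C, levels) histogram-domain penalty used by the
    membership update; levels with no pixels get 0.
    """
    gray = np.rint(image).astype(np.int64).ravel()
    counts = np.bincount(gray, minlength=levels).astype(float)
    C = factor_field.shape[0]
    gbar = np.zeros((C, levels))
    nonzero = counts > 0
    for q in range(C):
        sums = np.bincount(gray, weights=factor_field[q].ravel(),
                           minlength=levels)
        gbar[q, nonzero] = sums[nonzero] / counts[nonzero]
    return gbar


def update_memberships(
    centroids: np.ndarray,
    levels_values: np.ndarray,
    fuzziness: float,
    gbar: np.ndarray | None = None,
) -> np.ndarray:
    """Membership update: columns over clusters sum to 1.

    s_qz is proportional to (d_qz)^(-1/(v-1)) with
    d_qz = (xi_z - p_q)^2 + Gbar_qz.  Levels at zero distance to one or
    more centroids split their membership equally among those centroids.
    """
    centroids = np.asarray(centroids, dtype=float)
    if not np.all(np.isfinite(centroids)):
        raise ValueError("centroids must be finite")
    xi = np.asarray(levels_values, dtype=float)
    C, h = centroids.size, xi.size
    d = (xi[None, :] - centroids[:, None]) ** 2
    if gbar is not None:
        d = d + gbar
    S = np.empty((C, h))
    zero = d <= 0.0
    any_zero = zero.any(axis=0)
    with np.errstate(divide="ignore"):
        inv = d ** (-1.0 / (fuzziness - 1.0))
    inv[:, any_zero] = zero[:, any_zero].astype(float)
    S = inv / inv.sum(axis=0, keepdims=True)
    return S


def update_centroids(
    memberships: np.ndarray,
    counts: np.ndarray,
    levels_values: np.ndarray,
    fuzziness: float,
) -> np.ndarray:
    """Histogram-weighted centroid update.

    p_q = sum_z counts_z * s_qz^v * xi_z / sum_z counts_z * s_qz^v.  A
    starved cluster (zero denominator) is re-seeded at the most frequent
    gray level, with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("histogram has no mass")
    xi = np.asarray(levels_values, dtype=float)
    w = counts[None, :] * memberships ** fuzziness
    denom = w.sum(axis=1)
    num = w @ xi
    centroids = np.empty(memberships.shape[0])
    for q in range(centroids.size):
        if denom[q] <= 0.0:
            warnings.warn(f"cluster {q} starved; re-seeding at modal gray level")
            centroids[q] = xi[int(np.argmax(counts))]
        else:
            centroids[q] = num[q] / denom[q]
    return centroids


def objective(
    memberships: np.ndarray,
    centroids: np.ndarray,
    counts: np.ndarray,
    levels_values: np.ndarray,
    fuzziness: float,
    gbar: np.ndarray | None = None,
) -> float:
    """Histogram-domain clustering objective (distance term + fuzzy factor)."""
    xi = np.asarray(levels_values, dtype=float)
    d = (xi[None, :] - np.asarray(centroids, float)[:, None]) ** 2
    j = float(np.sum(counts[None, :] * memberships ** fuzziness * d))
    if gbar is not None:
        j += float(np.sum(gbar))
    return j


def _adaptive_wiener(plane: np.ndarray, window: int) -> np.ndarray:
    """Local-statistics Wiener filter with reflect boundaries.

    Noise power is estimated as the mean of the local variances; where the
    local variance falls below it the local mean is returned.
    """
    m = ndimage.uniform_filter(plane, size=window, mode="reflect")
    m2 = ndimage.uniform_filter(plane * plane, size=window, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    noise = float(var.mean())
    out = m.copy()
    strong = var > noise
    if np.any(strong):
        out[strong] = m[strong] + (1.0 - noise / var[strong]) \
            * (plane[strong] - m[strong])
    return out


def expand_memberships(memberships: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Lift the (C, levels) membership matrix to (C, H, W) pixel planes."""
    gray = np.rint(image).astype(np.int64)
    return memberships[:, gray]


def wiener_filter_membership(
    memberships: np.ndarray, image: np.ndarray, window: int = 3
) -> np.ndarray:
    """Expand memberships to the pixel grid, Wiener-filter each cluster
    plane, and renormalize so per-pixel memberships sum to 1."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(image.shape):
        raise ValueError("window exceeds image dimensions")
    planes = expand_memberships(memberships, image).astype(float)
    filtered = np.stack([_adaptive_wiener(p, window) for p in planes])
    filtered = np.clip(filtered, 0.0, None)
    total = filtered.sum(axis=0)
    flat = total <= 0.0
    if np.any(flat):
        filtered[:, flat] = 1.0 / filtered.shape[0]
        total = filtered.sum(axis=0)
    return filtered / total


def _init_centroids(
    counts: np.ndarray, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    """Evenly spaced centers over the occupied gray range, jittered.

    Histogram quantiles would place several centroids on a single
    dominant gray level (e.g. a large background), and coincident
    centroids never separate under the symmetric updates, so spacing is
    over [min, max] occupied levels instead.
    """
    occupied = np.flatnonzero(counts)
    lo, hi = float(occupied[0]), float(occupied[-1])
    targets = (np.arange(n_clusters) + 0.5) / n_clusters
    centroids = lo + targets * (hi - lo)
    centroids += rng.uniform(-0.5, 0.5, size=n_clusters)
    return np.sort(centroids)


def segment(image: np.ndarray, config: ClusterConfig) -> SegmentationResult:
    """Full segmentation pipeline; deterministic given ``config.seed``.

    Alternates membership and centroid updates until the max-abs centroid
    change drops below ``config.tol`` or ``config.max_iter`` is hit (the
    best-so-far state is returned with ``converged=False`` in that case).
    """
    config.validate()
    image = _check_image(image)
    rng = np.random.default_rng(config.seed)

    if config.use_reconstruction:
        recon = morphological_reconstruct(image, config.reconstruction_radius)
    else:
        recon = image
    counts = compute_gray_histogram(recon, config.levels).astype(float)
    xi = np.arange(config.levels, dtype=float)
    v = config.fuzziness

    centroids = _init_centroids(counts, config.n_clusters, rng)
    S = update_memberships(centroids, xi, v, None)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        if config.neighborhood_radius > 0:
            ffield = fuzzy_factor_field(S, centroids, recon, config)
            gbar = aggregate_fuzzy_factor(ffield, recon, config.levels)
        else:
            gbar = None
        S = update_memberships(centroids, xi, v, gbar)
        new_centroids = update_centroids(S, counts, xi, v)
        trace.append(objective(S, new_centroids, counts, xi, v, gbar))
        shift = float(np.max(np.abs(new_centroids - centroids)))
        centroids = new_centroids
        if shift < config.tol:
            converged = True
            break

    if config.use_wiener:
        pixel_memberships = wiener_filter_membership(
            S, recon, config.wiener_window)
    else:
        pixel_memberships = expand_memberships(S, recon)
    labels = np.argmax(pixel_memberships, axis=0)

    return SegmentationResult(
        labels=labels,
        memberships=pixel_memberships,
        memberships_gray=S,
        centroids=centroids,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )
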