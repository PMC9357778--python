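"""Gray-level co-occurrence matrix (GLCM) texture features with region
splitting.

Feature vectors concatenate six classical GLCM statistics (contrast,
dissimilarity, energy, homogeneity, entropy, correlation) over a set of
regions (whole image plus top/bottom and left/right halves, mimicking
coronal/sagittal splits of a head image) and a set of pixel offsets
(distance 1 at 0, 45, 90 and 135 degrees by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "contrast",
    "dissimilarity",
    "energy",
    "homogeneity",
    "entropy",
    "correlation",
)

#: distance-1 offsets at 0, 45, 90, 135 degrees as (row-shift, col-shift)
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

REGION_NAMES = ("whole", "top", "bottom", "left", "right")

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_OFFSETS",
    "REGION_NAMES",
    "TextureConfig",
    "quantize",
    "compute_glcm",
    "haralick_features",
    "split_planes",
    "extract_feature_vector",
    "feature_layout",
]


@dataclass
class TextureConfig:
    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    regions: tuple[str, ...] = REGION_NAMES
    symmetric: bool = True
    normalize: bool = True

    def validate(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        unknown = set(self.regions) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"unknown regions {sorted(unknown)}")


def quantize(
    image: np.ndarray,
    levels: int,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Linear binning into ``levels`` bins; a constant image maps to 0.

    By default bins span [min, max] of the image; pass ``value_range`` to
    bin against a fixed scale shared across images.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    image = np.asarray(image, dtype=float)
    lo, hi = (image.min(), image.max()) if value_range is None else value_range
    if hi == lo:
        return np.zeros(image.shape, dtype=np.int64)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    image: np.ndarray,
    offset: tuple[int, int],
    levels: int,
    symmetric: bool = True,
    normalize: bool = True,
) -> np.ndarray:
    """Co-occurrence matrix of gray-level pairs (p, p + offset).

    ``offset`` is a (row-shift, col-shift) pair.  In symmetric mode the
    transpose is added before normalization; in normalized mode entries
    sum to 1.
    """
    image = np.asarray(image)
    dr, dc = offset
    h, w = image.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} too large for shape {image.shape}")
    if image.min() < 0 or image.max() >= levels:
        raise ValueError("image must be quantized to the requested levels")

    # source and destination windows of the shifted overlap
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = image[r0:r1, c0:c1].ravel()
    dst = image[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()

    P = np.zeros((levels, levels), dtype=float)
    np.add.at(P, (src, dst), 1.0)
    if symmetric:
        P = P + P.T
    if normalize:
        total = P.sum()
        if total > 0:
            P = P / total
    return P


def haralick_features(glcm: np.ndarray) -> dict[str, float]:
    """Six classical GLCM statistics of a normalized co-occurrence matrix.

    Correlation is defined as 0 when either marginal standard deviation
    vanishes; 0*log(0) is taken as 0 in the entropy.
    """
    P = np.asarray(glcm, dtype=float)
    if not np.isclose(P.sum(), 1.0, atol=1e-9):
        raise ValueError("glcm must be normalized (entries summing to 1)")
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j

    contrast = float(np.sum(diff ** 2 * P))
    dissimilarity = float(np.sum(np.abs(diff) * P))
    energy = float(np.sum(P ** 2))
    homogeneity = float(np.sum(P / (1.0 + diff ** 2)))
    nz = P > 0
    entropy = float(-np.sum(P[nz] * np.log2(P[nz])))

    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.sum(np.arange(L) * pi))
    mu_j = float(np.sum(np.arange(L) * pj))
    var_i = float(np.sum((np.arange(L) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(L) - mu_j) ** 2 * pj))
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * P) / np.sqrt(var_i * var_j))

    return {
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
        "correlation": correlation,
    }


def split_planes(image: np.ndarray) -> dict[str, np.ndarray]:
    """Top/bottom and left/right halves; odd dimensions give the extra
    row or column to the first half."""
    image = np.asarray(image)
    h, w = image.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2 to split")
    rh = (h + 1) // 2
    cw = (w + 1) // 2
    return {
        "top": image[:rh, :],
        "bottom": image[rh:, :],
        "left": image[:, :cw],
        "right": image[:, cw:],
    }


def feature_layout(config: TextureConfig) -> list[tuple[str, tuple[int, int], str]]:
    """Deterministic (region, offset, feature) ordering of the vector."""
    return [
        (region, offset, name)
        for region in config.regions
        for offset in config.offsets
        for name in FEATURE_NAMES
    ]


def extract_feature_vector(
    image: np.ndarray, config: TextureConfig | None = None
) -> np.ndarray:
    """Concatenated GLCM features over regions and offsets.

    The image is quantized once (shared bins) and regions whose extent is
    smaller than an offset contribute zeros with a logged warning.
    """
    if config is None:
        config = TextureConfig()
    config.validate()
    q = quantize(image, config.levels)
    regions = {"whole": q}
    if any(r != "whole" for r in config.regions):
        regions.update(split_planes(q))

    values = []
    for region_name in config.regions:
        sub = regions[region_name]
        for offset in config.offsets:
            dr, dc = offset
            if abs(dr) >= sub.shape[0] or abs(dc) >= sub.shape[1]:
                logger.warning(
                    "region %s smaller than offset %s; features zeroed",
                    region_name, offset)
                values.extend([0.0] * len(FEATURE_NAMES))
                continue
            glcm = compute_glcm(sub, offset, config.levels,
                                symmetric=config.symmetric,
                                normalize=config.normalize)
            feats = haralick_features(glcm)
            values.extend(feats[name] for name in FEATURE_NAMES)
    return np.asarray(values)
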