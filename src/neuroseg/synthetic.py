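"""Synthetic head phantoms with ground truth.

An elliptical "head" of tissue-A containing a few tissue-B blobs on a dark
background, optionally with a bright irregular tumor blob, corrupted by
Gaussian, salt-and-pepper, or speckle noise.  Everything is a pure
function of its arguments including the seed, so segmentation and
classification are testable without external data.

Class gray values: background 10, tissue-A 100, tissue-B 170, tumor 230.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASS_GRAY",
    "NOISE_KINDS",
    "Phantom",
    "generate_phantom",
    "generate_classification_set",
]

CLASS_GRAY = np.array([10, 100, 170, 230], dtype=np.uint8)
NOISE_KINDS = ("none", "gaussian", "salt_pepper", "speckle")


@dataclass
class Phantom:
    image: np.ndarray              # (size, size) uint8
    truth: np.ndarray              # (size, size) int labels 0..3
    meta: dict = field(default_factory=dict)


def _irregular_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    rng: np.random.Generator,
    wobble: float = 0.25,
) -> np.ndarray:
    """Boolean mask of a blob whose polar radius is perturbed by a few
    random harmonics."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    theta = np.arctan2(dy, dx)
    amp = rng.uniform(-wobble, wobble, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    r = radius * (1.0 + sum(a * np.cos((m + 2) * theta + p)
                            for m, (a, p) in enumerate(zip(amp, phase))))
    return dy ** 2 + dx ** 2 <= r ** 2


def _render_truth(size: int, tumor: bool, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    truth = np.zeros((size, size), dtype=np.int64)
    cy = cx = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    a, b = 0.42 * size, 0.34 * size  # head semi-axes
    head = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    truth[head] = 1

    # tissue-B: a few elliptical blobs clipped to the head
    for _ in range(rng.integers(2, 5)):
        bc = (cy + rng.uniform(-0.25, 0.25) * size,
              cx + rng.uniform(-0.2, 0.2) * size)
        ra = rng.uniform(0.06, 0.14) * size
        rb = rng.uniform(0.06, 0.14) * size
        blob = ((yy - bc[0]) / ra) ** 2 + ((xx - bc[1]) / rb) ** 2 <= 1.0
        truth[blob & head] = 2

    meta: dict = {"tumor": bool(tumor)}
    if tumor:
        tc = (cy + rng.uniform(-0.18, 0.18) * size,
              cx + rng.uniform(-0.15, 0.15) * size)
        tr = rng.uniform(0.05, 0.15) * size
        blob = _irregular_blob((size, size), tc, tr, rng)
        truth[blob & head] = 3
        meta.update(tumor_center=tuple(map(float, tc)), tumor_radius=float(tr))
    return truth, meta


def _apply_noise(
    image: np.ndarray, kind: str, level: float, rng: np.random.Generator
) -> np.ndarray:
    x = image.astype(float)
    if kind == "none" or level == 0.0:
        return image.copy()
    if kind == "gaussian":
        x = x + rng.normal(0.0, level * 255.0, size=x.shape)
    elif kind == "salt_pepper":
        mask = rng.random(x.shape) < level
        salt = rng.random(x.shape) < 0.5
        x[mask & salt] = 255.0
        x[mask & ~salt] = 0.0
    elif kind == "speckle":
        x = x * (1.0 + rng.normal(0.0, level, size=x.shape))
    else:
        raise ValueError(f"unknown noise kind {kind!r}; one of {NOISE_KINDS}")
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def generate_phantom(
    size: int = 128,
    tumor: bool = False,
    noise_kind: str = "none",
    noise_level: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Render one phantom; fully reproducible from the arguments."""
    if size < 32:
        raise ValueError("size must be >= 32")
    if not (0.0 <= noise_level <= 0.5):
        raise ValueError("noise_level must lie in [0, 0.5]")
    if noise_kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {noise_kind!r}; one of {NOISE_KINDS}")
    rng = np.random.default_rng(seed)
    truth, meta = _render_truth(size, tumor, rng)
    clean = CLASS_GRAY[truth]
    image = _apply_noise(clean, noise_kind, noise_level, rng)
    meta.update(seed=seed, noise_kind=noise_kind, noise_level=noise_level,
                size=size)
    return Phantom(image=image, truth=truth, meta=meta)


def generate_classification_set(
    n_tumor: int,
    n_clean: int,
    size: int = 64,
    noise_kind: str = "gaussian",
    noise_level: float = 0.05,
    seed: int = 0,
) -> tuple[list[Phantom], np.ndarray]:
    """Shuffled tumor-present (label 1) and tumor-absent (label 0) phantoms
    with distinct seeds derived from the master seed."""
    if n_tumor < 1 or n_clean < 1:
        raise ValueError("n_tumor and n_clean must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_tumor + n_clean + 1)
    phantoms = []
    labels = []
    for i in range(n_tumor + n_clean):
        has_tumor = i < n_tumor
        child_seed = int(children[i].generate_state(1)[0])
        phantoms.append(generate_phantom(
            size=size, tumor=has_tumor, noise_kind=noise_kind,
            noise_level=noise_level, seed=child_seed))
        labels.append(1 if has_tumor else 0)
    order = np.random.default_rng(
        children[-1].generate_state(1)[0]).permutation(len(phantoms))
    phantoms = [phantoms[i] for i in order]
    labels = np.asarray(labels)[order]
    return phantoms, labels
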