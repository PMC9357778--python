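"""Readers/writers and the end-to-end pipeline.

Images are PNG/TIFF grayscale (8- or 16-bit; RGB is converted by
luminance with a log message); NIfTI volumes are read slice-wise along the
last axis.  Feature tables round-trip through CSV as decimal text with 17
significant digits, so values survive bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .elm import one_hot, predict
from .ifrfcm import ClusterConfig, SegmentationResult, segment
from .pso import SwarmConfig, pso_elm_train
from .synthetic import generate_classification_set
from .texture import TextureConfig, extract_feature_vector, feature_layout

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_labels",
    "read_features",
    "write_features",
    "read_nifti_slices",
    "PipelineConfig",
    "run_pipeline",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a 2-D integer gray grid."""
    path = Path(path)
    if path.suffix.lower() in (".nii", ".gz"):
        raise ValueError("use read_nifti_slices for NIfTI volumes")
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError(
            f"unsupported format {path.suffix!r}; supported: .png .tif .tiff")
    arr = iio.imread(path)
    if arr.ndim == 3:
        logger.info("converting RGB image %s to grayscale by luminance", path)
        arr = np.rint(
            0.2125 * arr[..., 0] + 0.7154 * arr[..., 1] + 0.0721 * arr[..., 2])
    return arr.astype(np.int64)


def read_nifti_slices(path: str | Path) -> list[np.ndarray]:
    """Ordered axial slices of a NIfTI volume, rescaled to 8-bit gray."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    lo, hi = vol.min(), vol.max()
    scaled = np.zeros_like(vol) if hi == lo else (vol - lo) / (hi - lo) * 255.0
    scaled = np.rint(scaled).astype(np.int64)
    return [scaled[..., k] for k in range(scaled.shape[-1])]


def write_labels(result: SegmentationResult, path: str | Path,
                 config: ClusterConfig | None = None) -> None:
    """Label map as PNG (one gray value per cluster) + JSON sidecar."""
    path = Path(path)
    n = result.centroids.size
    lut = np.linspace(0, 255, n).astype(np.uint8) if n > 1 \
        else np.array([255], dtype=np.uint8)
    iio.imwrite(path, lut[result.labels])
    sidecar = {
        "centroids": result.centroids.tolist(),
        "n_iter": result.n_iter,
        "converged": result.converged,
        "objective_trace": result.objective_trace,
        "config": None if config is None else asdict(config),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_features(vectors, path: str | Path, layout=None,
                   labels=None) -> None:
    """Feature table to CSV with 17 significant digits (lossless for
    doubles)."""
    arr = np.atleast_2d(np.asarray(vectors, dtype=float))
    if layout is None:
        columns = [f"f{i}" for i in range(arr.shape[1])]
    else:
        columns = [f"{region}_{dr}_{dc}_{name}"
                   for region, (dr, dc), name in layout]
    df = pd.DataFrame(arr, columns=columns)
    if labels is not None:
        df.insert(0, "label", np.asarray(labels, dtype=int))
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a feature CSV; returns (X, labels-or-None)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        raise ValueError(
            f"NaN in feature table at row {rows[0]}, "
            f"column {df.columns[cols[0]]!r}")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), labels


@dataclass
class PipelineConfig:
    """Configuration of the simulate -> segment -> features -> train ->
    predict -> evaluate pipeline; the master seed deterministically
    derives every stage seed."""

    outdir: str = "pipeline_out"
    n_tumor: int = 10
    n_clean: int = 10
    image_size: int = 64
    noise_kind: str = "gaussian"
    noise_level: float = 0.05
    train_fraction: float = 0.5
    n_hidden: int = 10
    n_particles: int = 20
    n_iterations: int = 50
    seed: int = 0
    segment_images: bool = False
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        cluster = ClusterConfig(**raw.pop("cluster", {}))
        tex_raw = raw.pop("texture", {})
        if "offsets" in tex_raw:
            tex_raw["offsets"] = tuple(tuple(o) for o in tex_raw["offsets"])
        if "regions" in tex_raw:
            tex_raw["regions"] = tuple(tex_raw["regions"])
        texture = TextureConfig(**tex_raw)
        return cls(cluster=cluster, texture=texture, **raw)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole workflow on a synthetic set and return the
    evaluation report; every artifact lands under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed}

    stage = "simulate"
    try:
        phantoms, labels = generate_classification_set(
            config.n_tumor, config.n_clean, size=config.image_size,
            noise_kind=config.noise_kind, noise_level=config.noise_level,
            seed=config.stage_seed(stage))
        manifest["stages"][stage] = {"seed": config.stage_seed(stage),
                                     "n": len(phantoms)}

        if config.segment_images:
            stage = "segment"
            seg_dir = out / "labels"
            seg_dir.mkdir(exist_ok=True)
            for i, ph in enumerate(phantoms):
                res = segment(ph.image, config.cluster)
                write_labels(res, seg_dir / f"phantom_{i:03d}.png",
                             config.cluster)
            manifest["stages"][stage] = {"n": len(phantoms)}

        stage = "features"
        X = np.stack([extract_feature_vector(ph.image, config.texture)
                      for ph in phantoms])
        layout = feature_layout(config.texture)
        write_features(X, out / "features.csv", layout, labels)
        manifest["stages"][stage] = {"n_features": X.shape[1]}

        stage = "split"
        rng = np.random.default_rng(config.stage_seed(stage))
        order = rng.permutation(len(phantoms))
        n_train = max(1, int(round(config.train_fraction * len(phantoms))))
        tr, va = order[:n_train], order[n_train:]
        if va.size == 0:
            raise ValueError("train_fraction leaves no validation samples")
        manifest["stages"][stage] = {"n_train": int(tr.size),
                                     "n_val": int(va.size)}

        stage = "train"
        swarm = SwarmConfig(
            n_particles=config.n_particles,
            dim=config.n_hidden * X.shape[1] + config.n_hidden,
            max_iter=config.n_iterations,
            seed=config.stage_seed(stage))
        model, history = pso_elm_train(
            X[tr], labels[tr], X[va], labels[va],
            n_hidden=config.n_hidden, config=swarm)
        model.to_json(out / "model.json")
        pd.DataFrame({"iteration": range(len(history)),
                      "best_fitness": history}).to_csv(
            out / "history.csv", index=False)

        stage = "predict"
        _, pred = predict(model, X[va])
        pd.DataFrame({"index": va, "predicted": pred,
                      "truth": labels[va]}).to_csv(
            out / "predictions.csv", index=False)

        stage = "evaluate"
        report = metrics_mod.evaluate(pred, labels[va])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
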