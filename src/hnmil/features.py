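"""Instance embeddings via a pluggable extractor contract.

An extractor is any object exposing ``input_kind`` ("patch2d" or
"subvolume3d"), ``embedding_dim`` and a deterministic ``map(array) -> vector``.
An adapter for a real pretrained backbone would own its input normalization
(channel replication, model-specific scaling) behind the same three
attributes.  The bundled toy extractor is a seeded random linear projection of
a coarsened instance followed by a tanh nonlinearity: deterministic, fast, and
sensitive to mean-intensity and variance differences so that synthetic risk
signals propagate into the embeddings.

Augmentation mirrors the stored-feature workflow: each instance gets one
augmented twin (random rotation in [0, 10] degrees, Gaussian blur with
probability 0.5) embedded at extraction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .preprocess import Patch2D, SubVolume3D

BLUR_SIGMA = 1.0
MAX_ROTATION_DEG = 10.0


@dataclass(frozen=True)
class ExtractorSpec:
    name: str = "toy"
    embedding_dim: int = 256
    input_kind: str = "patch2d"  # or "subvolume3d"
    normalization: str = "inputs already scaled to [0, 1]"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if self.input_kind not in ("patch2d", "subvolume3d"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")


@dataclass
class InstanceBag:
    patient_id: str
    embeddings: np.ndarray  # N x D, plain instances
    embeddings_aug: np.ndarray  # N x D, augmented twins, same order
    instance_meta: list = field(default_factory=list)
    label: Optional[int] = None
    endpoint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise ValueError("embeddings must be a nonempty N x D array")
        if self.embeddings.shape != self.embeddings_aug.shape:
            raise ValueError("plain and augmented embeddings must share shape")
        if not np.isfinite(self.embeddings).all():
            raise ValueError("embeddings must be finite")

    @property
    def n_instances(self) -> int:
        return self.embeddings.shape[0]


def draw_augmentation(rng: np.random.Generator) -> tuple[float, bool]:
    """Rotation angle uniform on [0, 10] degrees; blur coin at p = 0.5."""
    return float(rng.uniform(0.0, MAX_ROTATION_DEG)), bool(rng.random() < 0.5)


def apply_augmentation(
    arr: np.ndarray, angle_deg: float, blur: bool, sigma: float = BLUR_SIGMA
) -> np.ndarray:
    """In-plane rotation (bilinear, zero fill) and optional Gaussian blur."""
    out = ndimage.rotate(
        arr, angle_deg, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0
    )
    if blur:
        out = ndimage.gaussian_filter(out, sigma=sigma)
    return out.astype(np.float32)


def augment_patch(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    angle, blur = draw_augmentation(rng)
    return apply_augmentation(arr, angle, blur)


class ToyExtractor:
    """Seeded fixed random projection of coarse local moments of an instance.

    The instance is summarized on a coarse grid (16x16 for patches, 8x8x8 for
    subvolumes) by two channels — local mean and local standard deviation —
    so both intensity and texture (variance) differences in the input reach
    the embedding.  The flattened channels are projected with a fixed Gaussian
    matrix scaled by 1/sqrt(fan_in) and passed through tanh.
    """

    _COARSE = {"patch2d": (16, 16), "subvolume3d": (8, 8, 8)}

    def __init__(self, spec: ExtractorSpec):
        self.spec = spec
        self.name = spec.name
        self.input_kind = spec.input_kind
        self.embedding_dim = spec.embedding_dim
        shape = self._COARSE[spec.input_kind]
        fan_in = 2 * int(np.prod(shape))
        rng = np.random.default_rng(spec.seed)
        self._coarse_shape = shape
        self._projection = rng.standard_normal((fan_in, spec.embedding_dim)) / np.sqrt(
            fan_in
        )

    def _moments(self, arr: np.ndarray) -> np.ndarray:
        x = arr.astype(np.float64)
        shape = np.array(x.shape)
        coarse = np.array(self._coarse_shape)
        if (shape % coarse == 0).all():
            # exact block pooling, e.g. 224 = 16 * 14
            block = shape // coarse
            view = x
            for ax, (c, b) in enumerate(zip(coarse, block)):
                view = view.reshape(view.shape[:2 * ax] + (c, b) + view.shape[2 * ax + 1:])
            axes = tuple(2 * ax + 1 for ax in range(len(coarse)))
            mean = view.mean(axis=axes)
            mean_sq = (view**2).mean(axis=axes)
        else:
            # Gaussian anti-aliasing acts as the local window
            kw = dict(order=1, preserve_range=True)
            mean = resize(x, self._coarse_shape, **kw)
            mean_sq = resize(x**2, self._coarse_shape, **kw)
        std = np.sqrt(np.clip(mean_sq - mean**2, 0.0, None))
        return np.concatenate([mean.ravel(), std.ravel()])

    def map(self, arr: np.ndarray) -> np.ndarray:
        return np.tanh(self._moments(arr) @ self._projection)


def toy_extractor(spec: ExtractorSpec) -> ToyExtractor:
    return ToyExtractor(spec)


def _instance_array(inst) -> np.ndarray:
    if isinstance(inst, Patch2D):
        return inst.pixels
    if isinstance(inst, SubVolume3D):
        return inst.voxels
    return np.asarray(inst)


def _instance_kind(inst) -> str:
    if isinstance(inst, Patch2D):
        return "patch2d"
    if isinstance(inst, SubVolume3D):
        return "subvolume3d"
    return "patch2d" if np.asarray(inst).ndim == 2 else "subvolume3d"


def embed_bag(
    instances: Sequence,
    extractor,
    rng: np.random.Generator,
    patient_id: str = "",
    label: Optional[int] = None,
    endpoint: Optional[str] = None,
) -> InstanceBag:
    """Embed a patient's instances and their augmented twins, in order."""
    if len(instances) == 0:
        raise ValueError("cannot embed an empty instance list")
    meta = []
    plain_rows, aug_rows = [], []
    for inst in instances:
        kind = _instance_kind(inst)
        if kind != extractor.input_kind:
            raise ValueError(
                f"instance kind {kind!r} does not match extractor "
                f"input_kind {extractor.input_kind!r}"
            )
        arr = _instance_array(inst)
        plain_rows.append(extractor.map(arr))
        angle, blur = draw_augmentation(rng)
        aug_rows.append(extractor.map(apply_augmentation(arr, angle, blur)))
        if isinstance(inst, Patch2D):
            meta.append({"view": inst.view, "slice_index": inst.slice_index})
        elif isinstance(inst, SubVolume3D):
            meta.append({"center_voxel": list(inst.center_voxel)})
        else:
            meta.append({})
    E = np.vstack(plain_rows)
    if E.shape[1] != extractor.embedding_dim:
        raise ValueError("extractor returned wrong embedding dimension")
    if not patient_id and hasattr(instances[0], "patient_id"):
        patient_id = instances[0].patient_id
    return InstanceBag(
        patient_id=patient_id,
        embeddings=E,
        embeddings_aug=np.vstack(aug_rows),
        instance_meta=meta,
        label=label,
        endpoint=endpoint,
    )


def save_bag(bag: InstanceBag, directory: str | Path) -> Path:
    """One .npz (plain + augmented matrices) with a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{bag.patient_id}.npz"
    np.savez(path, embeddings=bag.embeddings, embeddings_aug=bag.embeddings_aug)
    sidecar = {
        "patient_id": bag.patient_id,
        "instance_meta": bag.instance_meta,
        "label": bag.label,
        "endpoint": bag.endpoint,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def load_bag(path: str | Path) -> InstanceBag:
    path = Path(path)
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return InstanceBag(
        patient_id=meta["patient_id"],
        embeddings=arrays["embeddings"],
        embeddings_aug=arrays["embeddings_aug"],
        instance_meta=meta["instance_meta"],
        label=meta["label"],
        endpoint=meta["endpoint"],
    )
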