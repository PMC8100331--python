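"""Dataset containers, readers and the synthetic cluster generator.

Every reader rescales intensities to [0, 1] at read time so that all
consumers of a :class:`LabeledDataset` see one convention (the learner's
default constants are calibrated at this scale).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SyntheticSpec",
    "read_idx",
    "read_csv",
    "write_csv",
    "make_synthetic",
]

_IDX_IMAGE_MAGIC = 0x00000803
_IDX_LABEL_MAGIC = 0x00000801


@dataclass
class LabeledDataset:
    """Samples as a (n, p) non-negative array in [0, 1] plus optional labels."""

    X: np.ndarray
    y: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if len(self.y) != self.X.shape[0]:
                raise ValueError("label count does not match sample count")
        if np.any(self.X < 0):
            raise ValueError("samples must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.y is None:
            raise ValueError("dataset has no labels")
        return np.unique(self.y)


@dataclass
class SyntheticSpec:
    """Recipe for a k-cluster non-negative dataset.

    Emulates the structure the competitive learner assumes: each class is
    a sparse non-negative prototype (an "intensity image") and samples are
    bounded-noise copies of it.

    Parameters
    ----------
    k : int
        Number of clusters (classes).
    p : int
        Feature dimension.
    per_class : int
        Samples generated per cluster.
    prototype_sparsity : float
        Fraction of active (non-zero) entries in each prototype.
    noise_sd : float
        Standard deviation of additive Gaussian noise, clipped to [0, 1].
    separation : float
        Minimum pairwise cosine *distance* between prototypes (1 - cosine
        similarity); enforced by rejection sampling.
    seed : int
        RNG seed; identical spec + seed -> identical dataset.
    """

    k: int = 10
    p: int = 196
    per_class: int = 500
    prototype_sparsity: float = 0.15
    noise_sd: float = 0.05
    separation: float = 0.8
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown synthetic-spec keys: {sorted(unknown)}")
        return cls(**d)


def _read_idx_header(buf: bytes, path: str, expected_magic: int, n_dims: int):
    need = 4 * (1 + n_dims)
    if len(buf) < need:
        raise ValueError(f"{path}: truncated IDX header (need {need} bytes, have {len(buf)})")
    magic = struct.unpack(">I", buf[:4])[0]
    if magic != expected_magic:
        raise ValueError(
            f"{path}: bad IDX magic 0x{magic:08x} at offset 0 (expected 0x{expected_magic:08x})"
        )
    dims = struct.unpack(">" + "I" * n_dims, buf[4:need])
    return dims, need


def read_idx(image_path: str | Path, label_path: str | Path) -> LabeledDataset:
    """Read an MNIST-style big-endian IDX image/label file pair.

    Pixels are flattened row-major to p = rows*cols and divided by 255.
    """
    image_path, label_path = Path(image_path), Path(label_path)
    ibuf = image_path.read_bytes()
    (n_img, rows, cols), off = _read_idx_header(ibuf, str(image_path), _IDX_IMAGE_MAGIC, 3)
    n_pix = n_img * rows * cols
    if len(ibuf) - off < n_pix:
        raise ValueError(f"{str(image_path)}: truncated pixel data at offset {off}")
    X = np.frombuffer(ibuf, dtype=np.uint8, count=n_pix, offset=off)
    X = X.reshape(n_img, rows * cols).astype(float) / 255.0

    lbuf = label_path.read_bytes()
    (n_lab,), loff = _read_idx_header(lbuf, str(label_path), _IDX_LABEL_MAGIC, 1)
    if n_lab != n_img:
        raise ValueError(f"image count {n_img} does not match label count {n_lab}")
    if len(lbuf) - loff < n_lab:
        raise ValueError(f"{str(label_path)}: truncated label data at offset {loff}")
    y = np.frombuffer(lbuf, dtype=np.uint8, count=n_lab, offset=loff).astype(int)
    meta = {"source": "idx", "image_file": str(image_path), "original_max": 255.0,
            "rows": rows, "cols": cols}
    return LabeledDataset(X=X, y=y, meta=meta)


def read_csv(path: str | Path, labeled: bool | None = None) -> LabeledDataset:
    """Read a samples-by-features CSV, optional trailing integer ``label`` column.

    Values are rescaled by the global maximum when it exceeds 1 so that
    arbitrary intensity scales land in [0, 1].
    """
    df = pd.read_csv(path)
    if labeled is None:
        labeled = df.columns[-1].lower() == "label"
    y = None
    if labeled:
        y = df.iloc[:, -1].to_numpy(dtype=int)
        df = df.iloc[:, :-1]
    X = df.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("CSV contains negative intensities")
    orig_max = float(X.max()) if X.size else 1.0
    if orig_max > 1.0:
        X = X / orig_max
    return LabeledDataset(X=X, y=y, meta={"source": str(path), "original_max": orig_max})


def write_csv(dataset: LabeledDataset, path: str | Path) -> None:
    """Write samples (and labels, when present) to a CSV round-trippable by read_csv."""
    df = pd.DataFrame(dataset.X, columns=[f"f{i}" for i in range(dataset.p)])
    if dataset.y is not None:
        df["label"] = dataset.y
    df.to_csv(path, index=False)


def _draw_prototypes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Sparse prototypes accepted one at a time against the separation bound."""
    n_active = max(1, round(spec.prototype_sparsity * spec.p))
    protos: list[np.ndarray] = []
    for _ in range(spec.k):
        for _attempt in range(1000):
            cand = np.zeros(spec.p)
            support = rng.choice(spec.p, size=n_active, replace=False)
            cand[support] = rng.uniform(0.5, 1.0, size=n_active)
            if not protos:
                protos.append(cand)
                break
            P = np.asarray(protos)
            sims = (P @ cand) / (np.linalg.norm(P, axis=1) * np.linalg.norm(cand))
            if 1.0 - sims.max() >= spec.separation:
                protos.append(cand)
                break
        else:
            raise ValueError(
                "infeasible separation: no prototype found in 1,000 rejection rounds")
    return np.asarray(protos)


def make_synthetic(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a k-cluster dataset of noisy copies of sparse prototypes.

    Each sample is its class prototype plus truncated additive Gaussian
    noise, clipped to [0, 1]; deterministic given the spec's seed.
    """
    if spec.k < 2 or spec.per_class < 1:
        raise ValueError("need k >= 2 clusters and per_class >= 1")
    rng = np.random.default_rng(spec.seed)
    protos = _draw_prototypes(spec, rng)
    n = spec.k * spec.per_class
    y = np.repeat(np.arange(spec.k), spec.per_class)
    X = protos[y] + rng.normal(0.0, spec.noise_sd, size=(n, spec.p))
    X = np.clip(X, 0.0, 1.0)
    # present clusters interleaved, as a shuffled stream would
    order = rng.permutation(n)
    meta = {"source": "synthetic", "spec": spec.to_dict(), "prototypes": protos,
            "original_max": 1.0}
    return LabeledDataset(X=X[order], y=y[order], meta=meta)
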