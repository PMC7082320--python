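"""Synthetic spike-train data: Poisson rate encoding and a rate-coded
multi-class task with known ground truth.

The generator emulates the structure of rate-coded classification inputs:
each class owns a template subset of input neurons that fire at a high
per-step probability while the rest fire at a low background probability.
Class templates may share a controllable fraction of neurons (``overlap``),
and every example is an independent Bernoulli (discrete Poisson) sample, so
the task has irreducible trial-to-trial noise but a known optimal decision
rule. An optional loader for the big-endian IDX container (the format MNIST
ships in) lets user-supplied image files drive the same pipeline; nothing is
downloaded.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateTaskSpec",
    "RateDataset",
    "poisson_encode",
    "center_crop",
    "make_rate_task",
    "load_idx_images",
    "load_idx_labels",
]


@dataclass(frozen=True)
class RateTaskSpec:
    """Parameters of the synthetic rate-coded classification task.

    ``base_rate`` and ``peak_rate`` are per-step spike probabilities of
    background and template neurons; ``overlap`` is the fraction of each
    class template shared with a common pool of neurons.
    """

    n_classes: int = 3
    n_inputs: int = 20
    T: int = 100
    base_rate: float = 0.02
    peak_rate: float = 0.2
    overlap: float = 0.2
    n_per_class: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate < self.peak_rate <= 1.0:
            raise ValueError("need 0 <= base_rate < peak_rate <= 1")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("need 0 <= overlap < 1")
        if self.n_classes < 2 or self.n_inputs < self.n_classes:
            raise ValueError("need >= 2 classes and at least one input per class")
        if self.T <= 0 or self.n_per_class <= 0:
            raise ValueError("T and n_per_class must be positive")


@dataclass
class RateDataset:
    """Labeled spike-train examples plus the generating ground truth.

    ``examples[i]`` is a boolean raster ``(n_inputs, T)``; ``templates[c]``
    is the boolean membership mask of class ``c``'s template neurons. The
    templates are the generator's ground truth: a classifier that counts
    spikes on each template achieves the task's best possible accuracy.
    """

    examples: list[np.ndarray]
    labels: np.ndarray
    templates: np.ndarray
    spec: RateTaskSpec

    def __len__(self) -> int:
        return len(self.examples)

    def template_classify(self, raster: np.ndarray) -> int:
        """Oracle decision rule: argmax of per-template mean spike counts."""
        counts = raster.sum(axis=1).astype(np.float64)
        scores = [counts[mask].mean() for mask in self.templates]
        return int(np.argmax(scores))


def poisson_encode(
    intensities, T: int, peak_rate: float = 0.2, seed: int = 0
) -> np.ndarray:
    """Encode intensities in [0, 1] as independent Bernoulli spike rasters.

    Each input neuron fires i.i.d. per step with probability
    ``intensity * peak_rate`` — the discrete-time realization of Poisson
    rate coding with ``dt = 1``. Returns a boolean raster ``(n, T)``.
    """
    intensities = np.asarray(intensities, dtype=np.float64).ravel()
    if np.any(intensities < 0) or np.any(intensities > 1):
        raise ValueError("intensities must lie in [0, 1]")
    if not 0 < peak_rate <= 1:
        raise ValueError("peak_rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    probs = intensities[:, np.newaxis] * peak_rate
    return rng.random((intensities.size, T)) < probs


def center_crop(image: np.ndarray, size: int = 14) -> np.ndarray:
    """Centered ``size x size`` window of a 2-D grid (even-margin convention:
    offset ``floor((dim - size)/2)`` on each axis)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    H, W = image.shape
    if size > H or size > W:
        raise ValueError(f"crop size {size} exceeds image shape {image.shape}")
    r0 = (H - size) // 2
    c0 = (W - size) // 2
    return image[r0 : r0 + size, c0 : c0 + size]


def make_rate_task(spec: RateTaskSpec) -> RateDataset:
    """Generate the labeled synthetic task; a pure function of ``spec``.

    Template construction: a shared pool of ``round(overlap * per_class)``
    neurons is common to all classes; the remaining template neurons of each
    class are disjoint. Class-``c`` examples fire template neurons at
    ``peak_rate`` and all others at ``base_rate``. Examples are ordered
    class-major (all of class 0, then class 1, ...).
    """
    rng = np.random.default_rng(spec.seed)
    per_class = spec.n_inputs // spec.n_classes
    n_shared = int(round(spec.overlap * per_class))
    n_own = per_class - n_shared
    needed = n_shared + n_own * spec.n_classes
    if per_class < 1 or needed > spec.n_inputs:
        raise ValueError("n_inputs too small for the requested class templates")

    perm = rng.permutation(spec.n_inputs)
    shared = perm[:n_shared]
    templates = np.zeros((spec.n_classes, spec.n_inputs), dtype=bool)
    pos = n_shared
    for c in range(spec.n_classes):
        own = perm[pos : pos + n_own]
        pos += n_own
        templates[c, shared] = True
        templates[c, own] = True

    examples: list[np.ndarray] = []
    labels: list[int] = []
    for c in range(spec.n_classes):
        probs = np.where(templates[c], spec.peak_rate, spec.base_rate)
        for _ in range(spec.n_per_class):
            examples.append(rng.random((spec.n_inputs, spec.T)) < probs[:, np.newaxis])
            labels.append(c)
    return RateDataset(
        examples=examples,
        labels=np.asarray(labels, dtype=np.int64),
        templates=templates,
        spec=spec,
    )


_IDX_DTYPES = {
    0x08: np.dtype(">u1"),
    0x09: np.dtype(">i1"),
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}


def _load_idx(path) -> np.ndarray:
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 4:
        raise ValueError(f"{path}: truncated IDX header")
    zero1, zero2, type_code, n_dims = struct.unpack(">BBBB", blob[:4])
    if zero1 != 0 or zero2 != 0 or type_code not in _IDX_DTYPES:
        raise ValueError(f"{path}: bad IDX magic number")
    header_end = 4 + 4 * n_dims
    if len(blob) < header_end:
        raise ValueError(f"{path}: truncated IDX dimension header")
    dims = struct.unpack(f">{n_dims}i", blob[4:header_end])
    dtype = _IDX_DTYPES[type_code]
    expected = int(np.prod(dims)) * dtype.itemsize
    payload = blob[header_end:]
    if len(payload) != expected:
        raise ValueError(
            f"{path}: payload has {len(payload)} bytes, header promises {expected}"
        )
    return np.frombuffer(payload, dtype=dtype).reshape(dims)


def load_idx_images(images_path, labels_path=None):
    """Read images (and optionally labels) from big-endian IDX files.

    Returns ``images`` of shape ``(n, H, W)``, or ``(images, labels)`` when
    ``labels_path`` is given; raises on bad magic numbers, truncation, or an
    image/label count mismatch. No download is ever performed.
    """
    images = _load_idx(images_path)
    if images.ndim != 3:
        raise ValueError(f"{images_path}: expected a rank-3 image tensor")
    if labels_path is None:
        return images
    labels = load_idx_labels(labels_path)
    if labels.shape[0] != images.shape[0]:
        raise ValueError(
            f"image/label count mismatch: {images.shape[0]} vs {labels.shape[0]}"
        )
    return images, labels


def load_idx_labels(path) -> np.ndarray:
    """Read a rank-1 IDX label vector."""
    labels = _load_idx(path)
    if labels.ndim != 1:
        raise ValueError(f"{path}: expected a rank-1 label vector")
    return labels
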