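"""Brownian distance covariance (BDC) pooling and trace-similarity classification.

The image metric branch represents each image by a *second-order* statistic:
the double-centered matrix of pairwise Euclidean distances between the
observation vectors of its backbone feature map.  Unlike a mean-pooled
(first-order) prototype, this matrix captures the dependence structure among
channels, which is what discriminates visually similar fine-grained classes
whose mean activations coincide.

Pipeline per image: feature map ``h x w x d`` -> observation matrix ->
pairwise Euclidean distance matrix -> double-centering -> BDC matrix.
Class prototypes are element-wise means of support BDC matrices, and a query
is assigned to the prototype with the largest Frobenius inner product
(``tr(A^T P)``, the "trace similarity").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FeatureMap",
    "DistanceMatrix",
    "BDCMatrix",
    "ClassPrototype",
    "reshape_feature_map",
    "pairwise_distance_matrix",
    "double_center",
    "bdc_representation",
    "class_prototype",
    "trace_similarity",
    "image_branch_probabilities",
]

#: absolute tolerance for the double-centering invariant
CENTERING_TOL = 1e-8

Axis = Literal["channel", "spatial"]


@dataclass(frozen=True)
class FeatureMap:
    """A backbone feature tensor of shape ``(h, w, d)`` for one image."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"feature map must be 3-D (h, w, d), got shape {v.shape}")
        h, w, d = v.shape
        if h * w < 2 or d < 2:
            raise ValueError(f"feature map needs h*w >= 2 and d >= 2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature map contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class DistanceMatrix:
    """Square matrix of pairwise Euclidean distances between observations."""

    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(v < 0) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be non-negative with zero diagonal")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BDCMatrix:
    """Double-centered distance matrix: every row and column sums to zero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("BDC matrix must be square")
        if not np.allclose(v, v.T, atol=CENTERING_TOL):
            raise ValueError("BDC matrix must be symmetric")
        if (
            np.abs(v.sum(axis=0)).max() > CENTERING_TOL * max(1.0, np.abs(v).max())
            or np.abs(v.sum(axis=1)).max() > CENTERING_TOL * max(1.0, np.abs(v).max())
        ):
            raise ValueError("BDC matrix rows/columns must sum to zero")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClassPrototype:
    """Element-wise mean of the support BDC matrices of one class."""

    matrix: BDCMatrix
    class_id: object = None
    support_count: int = 1

    def __post_init__(self) -> None:
        if self.support_count < 1:
            raise ValueError("support_count must be positive")


def reshape_feature_map(f: FeatureMap, axis: Axis = "channel") -> np.ndarray:
    """Reshape a feature map into a matrix of observation vectors.

    With ``axis="channel"`` (default) the *channels* are the observations:
    the result has ``d`` rows of length ``h*w``, and the downstream BDC
    matrix is ``d x d``.  With ``axis="spatial"`` the spatial positions are
    the observations (``h*w`` rows of length ``d``).
    """
    v = f.values
    h, w, d = v.shape
    flat = v.reshape(h * w, d)  # row = spatial location, col = channel
    if axis == "channel":
        return flat.T.copy()
    if axis == "spatial":
        return flat.copy()
    raise ValueError(f"axis must be 'channel' or 'spatial', got {axis!r}")


def pairwise_distance_matrix(vectors: Sequence[np.ndarray] | np.ndarray) -> DistanceMatrix:
    """Euclidean distance matrix between the given observation vectors."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("observations must form a 2-D array (ragged input?)")
    if arr.shape[0] < 2:
        raise ValueError("need at least two observation vectors")
    if not np.all(np.isfinite(arr)):
        raise ValueError("observations contain non-finite values")
    return DistanceMatrix(squareform(pdist(arr, metric="euclidean")))


def double_center(dm: DistanceMatrix) -> BDCMatrix:
    """Double-center a distance matrix.

    Each entry has its row mean and column mean subtracted and the grand
    mean added back, so every row and column of the result sums to zero.
    """
    a = dm.values
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    grand = a.mean()
    return BDCMatrix(a - row - col + grand)


def bdc_representation(f: FeatureMap, axis: Axis = "channel") -> BDCMatrix:
    """Full BDC representation: reshape, pairwise distances, double-center."""
    return double_center(pairwise_distance_matrix(reshape_feature_map(f, axis)))


def class_prototype(matrices: Sequence[BDCMatrix], class_id: object = None) -> ClassPrototype:
    """Element-wise mean of support BDC matrices (centering is preserved)."""
    if len(matrices) == 0:
        raise ValueError("cannot build a prototype from an empty support set")
    sizes = {m.size for m in matrices}
    if len(sizes) != 1:
        raise ValueError(f"support BDC matrices differ in size: {sorted(sizes)}")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ClassPrototype(BDCMatrix(mean), class_id=class_id, support_count=len(matrices))


def trace_similarity(a: BDCMatrix, p: ClassPrototype) -> float:
    """Frobenius inner product ``tr(a^T p)`` between query and prototype."""
    if a.size != p.matrix.size:
        raise ValueError(f"size mismatch: query {a.size} vs prototype {p.matrix.size}")
    return float(np.sum(a.values * p.matrix.values))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def image_branch_probabilities(
    query: BDCMatrix,
    prototypes: Sequence[ClassPrototype],
    scale_mode: Literal["zscore", "none"] = "zscore",
    temperature: float = 1.0,
) -> np.ndarray:
    """Class probabilities for a query from its trace similarities.

    Raw trace similarities grow with the matrix size and feature magnitude,
    so they are standardized across classes (z-score by default) before a
    temperature-scaled softmax.  Both steps are strictly increasing, so the
    argmax always equals the argmax of the raw similarities (ties resolve to
    the lowest class index, as ``numpy.argmax`` does).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if len(prototypes) < 2:
        raise ValueError("need at least two prototypes")
    sims = np.array([trace_similarity(query, p) for p in prototypes])
    if scale_mode == "zscore":
        sd = sims.std()
        logits = (sims - sims.mean()) / sd if sd > 0 else np.zeros_like(sims)
    elif scale_mode == "none":
        logits = sims
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    return _softmax(logits / temperature)
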