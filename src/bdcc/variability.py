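"""Intra-class image variability: six statistics, normalization, ranking.

For each class-grouped image set, six statistics quantify how dissimilar
images of the same class are:

* ``avg_euclidean`` — mean Euclidean distance between pairwise feature
  embeddings (default embedder: flattened resized grayscale pixels);
* ``avg_cosine`` — mean cosine *dissimilarity* (1 - cosine similarity)
  between the same embeddings, so higher always means more variable;
* ``avg_variance`` — mean per-image pixel variance (detail/contrast);
* ``avg_ssim`` — mean pairwise structural similarity (lower = more variable);
* ``avg_psnr`` — mean pairwise peak signal-to-noise ratio in dB, with
  identical pairs capped at a finite value (lower = more variable);
* ``avg_color_std`` — mean per-image standard deviation of channel means
  (color richness).

Dataset-level vectors are unweighted means over per-class vectors.  To
compare datasets, each statistic is min-max normalized across datasets and
the similarity-oriented ones (SSIM, PSNR) are inverted so that higher
normalized values always indicate more intra-class variability; the overall
dissimilarity score is the mean of the six normalized entries and datasets
are ranked by it in descending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from skimage.transform import resize

__all__ = [
    "ClassImageSet",
    "MetricVector",
    "VariabilityConfig",
    "METRIC_NAMES",
    "InsufficientImagesError",
    "pairwise_image_metrics",
    "compute_dataset_metrics",
    "normalize_metrics",
    "overall_dissimilarity",
    "rank_datasets",
    "dataset_variability_report",
    "load_dataset",
]

METRIC_NAMES = (
    "avg_euclidean",
    "avg_cosine",
    "avg_variance",
    "avg_ssim",
    "avg_psnr",
    "avg_color_std",
)

#: statistics where a *lower* raw value means more intra-class variability
INVERTED_METRICS = ("avg_ssim", "avg_psnr")


class InsufficientImagesError(ValueError):
    """Fewer images than the pairwise statistics require."""


@dataclass
class ClassImageSet:
    """Images of one class, as float arrays in [0, 1] or uint8 arrays."""

    class_id: str
    images: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError(f"class {self.class_id!r} has no images")


@dataclass(frozen=True)
class MetricVector:
    """The six intra-class variability statistics."""

    avg_euclidean: float
    avg_cosine: float
    avg_variance: float
    avg_ssim: float
    avg_psnr: float
    avg_color_std: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in METRIC_NAMES])


@dataclass(frozen=True)
class VariabilityConfig:
    """Preprocessing and sampling settings for the pairwise statistics.

    ``resize`` — common square side for grayscale comparisons;
    ``pairs_cap`` — at most this many unordered pairs per class (seeded
    subsample beyond); ``psnr_cap`` — finite substitute, in dB, for the
    infinite PSNR of identical images.
    """

    resize: int = 128
    pairs_cap: int = 200
    psnr_cap: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resize < 8 or self.pairs_cap < 1 or self.psnr_cap <= 0:
            raise ValueError("invalid variability configuration")


def _to_float(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if a.dtype == np.uint8:
        return a.astype(float) / 255.0
    return a.astype(float)


def _gray(img: np.ndarray, side: int) -> np.ndarray:
    a = _to_float(img)
    if a.ndim == 3:
        a = rgb2gray(a)
    if a.shape != (side, side):
        a = resize(a, (side, side), anti_aliasing=True)
    return a


def default_embedder(side: int) -> Callable[[np.ndarray], np.ndarray]:
    """Embed an image as its flattened resized grayscale pixels."""

    def embed(img: np.ndarray) -> np.ndarray:
        return _gray(img, side).ravel()

    return embed


def _cosine_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 and nb == 0:
        return 0.0
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - np.dot(a, b) / (na * nb))


def _sample_pairs(
    n: int, cap: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) <= cap:
        return pairs
    idx = rng.choice(len(pairs), size=cap, replace=False)
    return [pairs[i] for i in sorted(idx)]


def pairwise_image_metrics(
    image_set: ClassImageSet,
    embedder: Callable[[np.ndarray], np.ndarray] | None = None,
    config: VariabilityConfig = VariabilityConfig(),
) -> MetricVector:
    """Six variability statistics for one class's images.

    Pairwise statistics run over all unordered pairs, or a seeded subsample
    of ``config.pairs_cap`` pairs for large classes; per-image statistics
    (variance, color std) average over every image.
    """
    images = image_set.images
    if len(images) < 2:
        raise InsufficientImagesError(
            f"class {image_set.class_id!r} has {len(images)} image(s); "
            "pairwise statistics need at least 2"
        )
    embed = embedder if embedder is not None else default_embedder(config.resize)

    grays = [_gray(im, config.resize) for im in images]
    embeds = [np.asarray(embed(im), dtype=float).ravel() for im in images]
    rng = np.random.default_rng(config.seed)
    pairs = _sample_pairs(len(images), config.pairs_cap, rng)

    eucl, cosd, ssims, psnrs = [], [], [], []
    for i, j in pairs:
        eucl.append(float(np.linalg.norm(embeds[i] - embeds[j])))
        cosd.append(_cosine_dissimilarity(embeds[i], embeds[j]))
        ssims.append(
            float(structural_similarity(grays[i], grays[j], data_range=1.0))
        )
        mse = float(np.mean((grays[i] - grays[j]) ** 2))
        if mse == 0:
            psnrs.append(config.psnr_cap)
        else:
            psnrs.append(
                min(
                    float(peak_signal_noise_ratio(grays[i], grays[j], data_range=1.0)),
                    config.psnr_cap,
                )
            )

    variances = [float(g.var()) for g in grays]
    color_stds = []
    for im in images:
        a = _to_float(im)
        if a.ndim == 3 and a.shape[2] > 1:
            color_stds.append(float(np.std(a.mean(axis=(0, 1)))))
        else:
            color_stds.append(0.0)

    return MetricVector(
        avg_euclidean=float(np.mean(eucl)),
        avg_cosine=float(np.mean(cosd)),
        avg_variance=float(np.mean(variances)),
        avg_ssim=float(np.mean(ssims)),
        avg_psnr=float(np.mean(psnrs)),
        avg_color_std=float(np.mean(color_stds)),
    )


def compute_dataset_metrics(
    class_sets: Sequence[ClassImageSet],
    embedder: Callable[[np.ndarray], np.ndarray] | None = None,
    config: VariabilityConfig = VariabilityConfig(),
) -> MetricVector:
    """Unweighted mean of per-class metric vectors (classes with >= 2 images)."""
    usable = [cs for cs in class_sets if len(cs.images) >= 2]
    if not usable:
        raise InsufficientImagesError("no class has the >= 2 images pairwise metrics need")
    arrays = [
        pairwise_image_metrics(cs, embedder=embedder, config=config).as_array()
        for cs in usable
    ]
    mean = np.mean(arrays, axis=0)
    return MetricVector(*mean)


def normalize_metrics(raw: Sequence[MetricVector]) -> list[np.ndarray]:
    """Min-max normalize each statistic across datasets, inverting SSIM/PSNR.

    After normalization higher always means more intra-class variability.
    A statistic that is constant across datasets maps to 0.5 everywhere.
    """
    if len(raw) < 2:
        raise ValueError("normalization needs at least two datasets")
    mat = np.vstack([mv.as_array() for mv in raw])
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    span = hi - lo
    norm = np.where(span > 0, (mat - lo) / np.where(span > 0, span, 1.0), 0.5)
    for name in INVERTED_METRICS:
        k = METRIC_NAMES.index(name)
        norm[:, k] = 1.0 - norm[:, k] if span[k] > 0 else 0.5
    return [norm[i] for i in range(norm.shape[0])]


def overall_dissimilarity(normalized: np.ndarray) -> float:
    """Overall score: arithmetic mean of the six normalized statistics."""
    v = np.asarray(normalized, dtype=float)
    if v.shape != (len(METRIC_NAMES),):
        raise ValueError(f"expected {len(METRIC_NAMES)} normalized entries")
    return float(v.mean())


def rank_datasets(scores: Mapping[str, float]) -> list[str]:
    """Dataset names ordered by descending score; ties broken by name."""
    return [name for name, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]


def dataset_variability_report(
    datasets: Mapping[str, Sequence[ClassImageSet]],
    embedder: Callable[[np.ndarray], np.ndarray] | None = None,
    config: VariabilityConfig = VariabilityConfig(),
) -> pd.DataFrame:
    """Raw metrics, normalized metrics, overall score and rank per dataset.

    Rows are ordered by rank (most variable dataset first).
    """
    names = sorted(datasets)
    raw = [compute_dataset_metrics(datasets[n], embedder, config) for n in names]
    norm = normalize_metrics(raw)
    scores = {n: overall_dissimilarity(v) for n, v in zip(names, norm)}
    order = rank_datasets(scores)
    rows = []
    for n, mv, nv in zip(names, raw, norm):
        row = {"dataset": n}
        row.update({k: getattr(mv, k) for k in METRIC_NAMES})
        row.update({f"norm_{k}": v for k, v in zip(METRIC_NAMES, nv)})
        row["overall_score"] = scores[n]
        row["rank"] = order.index(n) + 1
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
    return df


def load_dataset(root: str | Path) -> list[ClassImageSet]:
    """Read one dataset directory: one subdirectory of PNG/JPEG per class."""
    import imageio.v3 as iio

    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    sets = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        files = sorted(
            p
            for p in class_dir.iterdir()
            if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
        )
        if files:
            sets.append(
                ClassImageSet(
                    class_id=class_dir.name, images=[iio.imread(f) for f in files]
                )
            )
    if not sets:
        raise InsufficientImagesError(f"no class directories with images under {root}")
    return sets
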