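"""Episodic N-way K-shot evaluation over class-structured datasets.

Datasets live on disk as one directory per class whose image files are
named with the hierarchical taxonomic convention
``Phylum_Family_Genus species`` (an optional ``__<k>`` index suffix is
ignored).  Classes are split 3:1:1 into train/validation/test with no
class overlap, after filtering out classes with too few images (at least
3 for 1-shot work, at least 7 for 5-shot).  Episodes are sampled from one
partition: N classes, K support and q query images per class, support and
query disjoint.

``run_episode`` executes the full two-branch pipeline on one episode:
support-set losses -> dynamic fusion weights -> smoothing -> fused query
predictions.  ``evaluate`` aggregates accuracy over an episode stream with
a normal-approximation 95% confidence interval, and ``evaluate_ablation``
replays the identical stream under each fusion strategy.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fusion import (
    DEFAULT_BETA,
    DEFAULT_EPSILON,
    FusionWeights,
    ModalityLosses,
    confidence_weights,
    dynamic_weights,
    fuse_predictions,
    smooth_weights,
    support_set_loss,
    unimodal_weights,
)

__all__ = [
    "TaxonomicLabel",
    "TaxonomyFormatError",
    "InsufficientDataError",
    "DatasetIndex",
    "SplitSpec",
    "Episode",
    "FusionConfig",
    "EpisodeResult",
    "EvaluationReport",
    "parse_taxonomy",
    "index_directory",
    "split_classes",
    "sample_episode",
    "run_episode",
    "evaluate",
    "evaluate_ablation",
    "FUSION_STRATEGIES",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}

#: fusion strategies exercised by the ablation harness
FUSION_STRATEGIES = ("fixed", "confidence", "support_loss", "support_loss_smoothed")


class TaxonomyFormatError(ValueError):
    """A file name does not follow the Phylum_Family_Genus-species convention."""


class InsufficientDataError(ValueError):
    """Not enough classes or images to satisfy the requested protocol."""


@dataclass(frozen=True)
class TaxonomicLabel:
    """Hierarchical label parsed from a file name: phylum, family, binomial."""

    phylum: str
    family: str
    genus_species: str

    def __post_init__(self) -> None:
        if not (self.phylum and self.family and self.genus_species):
            raise TaxonomyFormatError("taxonomic fields must be non-empty")
        if " " not in self.genus_species:
            raise TaxonomyFormatError(
                f"genus_species {self.genus_species!r} is not a binomial (no space)"
            )


_INDEX_SUFFIX = re.compile(r"__\d+$")


def parse_taxonomy(filename: str) -> TaxonomicLabel:
    """Parse ``Phylum_Family_Genus species`` from a file name.

    The extension and any trailing ``__<k>`` duplicate-index suffix are
    stripped; the name is then split on its first two underscores, so the
    species part may itself contain spaces or underscores.
    """
    stem = Path(filename).name
    if "." in stem:
        stem = stem[: stem.rindex(".")]
    stem = _INDEX_SUFFIX.sub("", stem)
    parts = stem.split("_", 2)
    if len(parts) < 3:
        raise TaxonomyFormatError(
            f"file {filename!r}: expected at least two underscores "
            "(Phylum_Family_Genus species)"
        )
    try:
        return TaxonomicLabel(phylum=parts[0], family=parts[1], genus_species=parts[2])
    except TaxonomyFormatError as exc:
        raise TaxonomyFormatError(f"file {filename!r}: {exc}") from None


@dataclass(frozen=True)
class DatasetIndex:
    """Per-class item lists, keyed by class id."""

    classes: Mapping[str, tuple[TaxonomicLabel | None, tuple[str, ...]]]

    def __post_init__(self) -> None:
        if not self.classes:
            raise InsufficientDataError("dataset index is empty")
        seen: set[str] = set()
        for cid, (_, items) in self.classes.items():
            if not items:
                raise InsufficientDataError(f"class {cid!r} has no items")
            for it in items:
                if it in seen:
                    raise ValueError(f"item id {it!r} appears in more than one class")
                seen.add(it)
        object.__setattr__(self, "classes", dict(self.classes))

    def items_of(self, class_id: str) -> tuple[str, ...]:
        return self.classes[class_id][1]

    def class_ids(self) -> list[str]:
        return sorted(self.classes)


def index_directory(root: str | Path) -> DatasetIndex:
    """Index a ``root/<class_dir>/<image files>`` tree.

    The taxonomic label of each class is parsed from its first item's file
    name; items within a class are stored in lexicographic order so seeded
    sampling is independent of filesystem enumeration order.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    classes: dict[str, tuple[TaxonomicLabel | None, tuple[str, ...]]] = {}
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        files = sorted(
            str(p.relative_to(root))
            for p in class_dir.iterdir()
            if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            continue
        label = parse_taxonomy(files[0])
        classes[class_dir.name] = (label, tuple(files))
    return DatasetIndex(classes)


@dataclass(frozen=True)
class SplitSpec:
    """Class-disjoint 3:1:1 train/val/test split over eligible classes."""

    train: frozenset[str]
    val: frozenset[str]
    test: frozenset[str]
    ratio: tuple[int, int, int] = (3, 1, 1)
    min_images: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train & self.val or self.train & self.test or self.val & self.test:
            raise ValueError("split partitions must be pairwise disjoint")

    def partition(self, name: str) -> frozenset[str]:
        return {"train": self.train, "val": self.val, "test": self.test}[name]


def split_classes(index: DatasetIndex, min_images: int, seed: int) -> SplitSpec:
    """Shuffle eligible classes (count >= min_images) and assign 3:1:1.

    Remainder classes after the integer division go to the training
    partition.  Deterministic for a fixed seed.
    """
    eligible = sorted(
        cid for cid in index.classes if len(index.items_of(cid)) >= min_images
    )
    if len(eligible) < 5:
        raise InsufficientDataError(
            f"need at least 5 classes with >= {min_images} images, found {len(eligible)}"
        )
    rng = np.random.default_rng(seed)
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    n = len(order)
    n_val = n // 5
    n_test = n // 5
    n_train = n - n_val - n_test
    return SplitSpec(
        train=frozenset(order[:n_train]),
        val=frozenset(order[n_train : n_train + n_val]),
        test=frozenset(order[n_train + n_val :]),
        min_images=min_images,
        seed=seed,
    )


@dataclass(frozen=True)
class Episode:
    """One N-way K-shot task: labeled support items plus query items.

    ``class_ids`` fixes the order of the episode's classes; labels in
    ``support`` and ``query`` are indices into it.
    """

    n_way: int
    k_shot: int
    q: int
    class_ids: tuple[str, ...]
    support: tuple[tuple[str, int], ...]
    query: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.n_way < 2 or self.k_shot < 1 or self.q < 1:
            raise ValueError("need n_way >= 2, k_shot >= 1, q >= 1")
        if len(self.class_ids) != self.n_way:
            raise ValueError("class_ids length must equal n_way")
        sup_items = [it for it, _ in self.support]
        qry_items = [it for it, _ in self.query]
        if set(sup_items) & set(qry_items):
            raise ValueError("support and query sets overlap")
        for lst, per_class, name in (
            (self.support, self.k_shot, "support"),
            (self.query, self.q, "query"),
        ):
            counts = np.bincount([c for _, c in lst], minlength=self.n_way)
            if len(lst) != per_class * self.n_way or not np.all(counts == per_class):
                raise ValueError(f"{name} set must hold {per_class} items per class")

    @property
    def support_labels(self) -> np.ndarray:
        return np.array([c for _, c in self.support])

    @property
    def query_labels(self) -> np.ndarray:
        return np.array([c for _, c in self.query])


def sample_episode(
    index: DatasetIndex,
    partition: Iterable[str],
    n_way: int,
    k_shot: int,
    q: int,
    rng: np.random.Generator,
) -> Episode:
    """Sample an N-way K-shot episode from one split partition.

    Classes and items are drawn without replacement; items are sorted
    lexicographically before the seeded draw so the result depends only on
    the generator state.
    """
    if q == 1:
        warnings.warn(
            "q=1 gives a single query per class; episode accuracies are "
            "coarse and unreliable",
            stacklevel=2,
        )
    need = k_shot + q
    candidates = sorted(set(partition) & set(index.classes))
    eligible = [c for c in candidates if len(index.items_of(c)) >= need]
    if len(eligible) < n_way:
        short = [c for c in candidates if c not in eligible]
        detail = f"; e.g. class {short[0]!r} has fewer than {need} items" if short else ""
        raise InsufficientDataError(
            f"only {len(eligible)} classes have >= {need} items, "
            f"need {n_way}{detail}"
        )
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=n_way, replace=False)]
    support: list[tuple[str, int]] = []
    query: list[tuple[str, int]] = []
    for ci, cid in enumerate(chosen):
        items = sorted(index.items_of(cid))
        picked = [items[i] for i in rng.choice(len(items), size=need, replace=False)]
        support.extend((it, ci) for it in picked[:k_shot])
        query.extend((it, ci) for it in picked[k_shot:])
    return Episode(
        n_way=n_way,
        k_shot=k_shot,
        q=q,
        class_ids=tuple(chosen),
        support=tuple(support),
        query=tuple(query),
    )


# A branch maps an episode to (support_probs, query_probs), each an array
# with one row per item and one column per episode class.
Branch = Callable[[Episode], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class FusionConfig:
    """How the two branches are combined within an episode."""

    strategy: str = "support_loss_smoothed"
    beta: float = DEFAULT_BETA
    epsilon: float = DEFAULT_EPSILON
    loo_support_loss: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in FUSION_STRATEGIES:
            raise ValueError(
                f"strategy must be one of {FUSION_STRATEGIES}, got {self.strategy!r}"
            )
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


@dataclass(frozen=True)
class EpisodeResult:
    """Predictions and diagnostics for one evaluated episode."""

    fused_probs: np.ndarray
    predicted: np.ndarray
    weights: FusionWeights
    loss_img: float | None
    loss_txt: float | None
    query_probs_img: np.ndarray | None
    query_probs_txt: np.ndarray | None
    accuracy: float


def _branch_probs(branch: Branch, ep: Episode, loo: bool) -> tuple[np.ndarray, np.ndarray]:
    """(support, query) predictions; support is leave-one-out when requested
    and the branch provides it (meaningful only for K >= 2)."""
    sup, qry = branch(ep)
    if loo and ep.k_shot >= 2 and hasattr(branch, "support_loo"):
        sup = branch.support_loo(ep)  # type: ignore[attr-defined]
    return sup, qry


def run_episode(
    ep: Episode,
    image_branch: Branch | None,
    text_branch: Branch | None,
    cfg: FusionConfig = FusionConfig(),
) -> EpisodeResult:
    """Run both branches on one episode and fuse their query predictions.

    With a single branch the fusion degenerates to that branch's output
    (unimodal operation).  Otherwise the support-set performance of each
    branch determines the weights according to ``cfg.strategy``.
    """
    if image_branch is None and text_branch is None:
        raise ValueError("at least one branch must be configured")
    labels = ep.query_labels

    if image_branch is None or text_branch is None:
        mode = "image_only" if text_branch is None else "text_only"
        branch = image_branch if image_branch is not None else text_branch
        _, qry = branch(ep)  # type: ignore[misc]
        fw = unimodal_weights(mode)
        pred = qry.argmax(axis=1)
        return EpisodeResult(
            fused_probs=qry,
            predicted=pred,
            weights=fw,
            loss_img=None,
            loss_txt=None,
            query_probs_img=qry if mode == "image_only" else None,
            query_probs_txt=qry if mode == "text_only" else None,
            accuracy=float(np.mean(pred == labels)),
        )

    sup_img, qry_img = _branch_probs(image_branch, ep, cfg.loo_support_loss)
    sup_txt, qry_txt = _branch_probs(text_branch, ep, cfg.loo_support_loss)
    sup_labels = ep.support_labels
    l_img = support_set_loss(list(sup_img), list(sup_labels))
    l_txt = support_set_loss(list(sup_txt), list(sup_labels))

    if cfg.strategy == "fixed":
        fw = FusionWeights(alpha_img=0.5, alpha_txt=0.5, stage="normalized")
    elif cfg.strategy == "confidence":
        fw = confidence_weights(list(sup_img), list(sup_txt))
    else:
        fw = dynamic_weights(ModalityLosses(l_img, l_txt, epsilon=cfg.epsilon))
        if cfg.strategy == "support_loss_smoothed":
            fw = smooth_weights(fw, cfg.beta)

    fused = np.vstack(
        [fuse_predictions(pi, pt, fw) for pi, pt in zip(qry_img, qry_txt)]
    )
    pred = fused.argmax(axis=1)
    return EpisodeResult(
        fused_probs=fused,
        predicted=pred,
        weights=fw,
        loss_img=l_img,
        loss_txt=l_txt,
        query_probs_img=qry_img,
        query_probs_txt=qry_txt,
        accuracy=float(np.mean(pred == labels)),
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregate accuracy over an episode stream.

    ``ci95`` is the normal-approximation half-width over per-episode
    accuracies; ``std`` is their standard deviation.
    """

    episodes: int
    mean_accuracy: float
    ci95: float
    std: float
    per_episode: pd.DataFrame

    def summary(self) -> dict:
        return {
            "episodes": self.episodes,
            "mean_accuracy": self.mean_accuracy,
            "ci95": self.ci95,
            "std": self.std,
        }


EpisodeTask = tuple[Episode, Branch | None, Branch | None]


def evaluate(
    tasks: Sequence[EpisodeTask], cfg: FusionConfig = FusionConfig()
) -> EvaluationReport:
    """Run the pipeline over a stream of episode tasks and aggregate accuracy."""
    if len(tasks) < 1:
        raise ValueError("need at least one episode")
    records = []
    for i, (ep, ib, tb) in enumerate(tasks):
        res = run_episode(ep, ib, tb, cfg)
        records.append(
            {
                "episode_id": i,
                "accuracy": res.accuracy,
                "alpha_img": res.weights.alpha_img,
                "alpha_txt": res.weights.alpha_txt,
                "loss_img": res.loss_img,
                "loss_txt": res.loss_txt,
            }
        )
    df = pd.DataFrame.from_records(records)
    accs = df["accuracy"].to_numpy()
    n = len(accs)
    std = float(accs.std(ddof=1)) if n > 1 else 0.0
    return EvaluationReport(
        episodes=n,
        mean_accuracy=float(accs.mean()),
        ci95=float(1.96 * std / np.sqrt(n)) if n > 1 else 0.0,
        std=std,
        per_episode=df,
    )


def evaluate_ablation(
    tasks: Sequence[EpisodeTask],
    strategies: Sequence[str] = FUSION_STRATEGIES,
    beta: float = DEFAULT_BETA,
    epsilon: float = DEFAULT_EPSILON,
    include_unimodal: bool = True,
) -> dict[str, EvaluationReport]:
    """Replay one fixed episode stream under each fusion strategy.

    Optionally adds ``image_only`` and ``text_only`` arms so the fused
    strategies can be compared against each branch alone.
    """
    out: dict[str, EvaluationReport] = {}
    for strat in strategies:
        cfg = FusionConfig(strategy=strat, beta=beta, epsilon=epsilon)
        out[strat] = evaluate(tasks, cfg)
    if include_unimodal:
        out["image_only"] = evaluate([(ep, ib, None) for ep, ib, _ in tasks])
        out["text_only"] = evaluate([(ep, None, tb) for ep, _, tb in tasks])
    return out
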