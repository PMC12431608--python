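"""Branch builders: turn embedding/feature-map providers into episode branches.

A branch is a callable ``episode -> (support_probs, query_probs)`` where each
array has one row per item and one column per episode class.  Builders here
wire the two concrete branches of the framework:

* the image metric branch, either nearest-prototype over plain embedding
  vectors or BDC trace-similarity over backbone feature maps;
* the zero-shot text branch, matching encoder image embeddings against the
  encoded compound prompts of the episode's classes.

Image branches additionally expose ``support_loo`` (leave-one-out support
predictions for K >= 2), used by the optional unbiased support-loss mode.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np

from .bdc import (
    BDCMatrix,
    ClassPrototype,
    FeatureMap,
    bdc_representation,
    class_prototype,
    image_branch_probabilities,
)
from .episodes import Episode
from .prompts import (
    EncoderPair,
    PromptLibrary,
    TextBranchConfig,
    encode_class_prompts,
    text_branch_probabilities,
)

__all__ = [
    "embedding_prototype_branch",
    "bdc_image_branch",
    "text_branch",
]


class _Branch:
    """Callable branch with an optional leave-one-out support method."""

    def __init__(self, predict, support_loo=None):
        self._predict = predict
        if support_loo is not None:
            self.support_loo = support_loo

    def __call__(self, ep: Episode):
        return self._predict(ep)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _zscore_rows(scores: np.ndarray) -> np.ndarray:
    sd = scores.std(axis=1, keepdims=True)
    centered = scores - scores.mean(axis=1, keepdims=True)
    return np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)


def embedding_prototype_branch(
    vectors: Mapping[str, np.ndarray], temperature: float = 1.0
) -> _Branch:
    """Nearest-prototype classifier over embedding vectors.

    Class prototypes are the mean support vectors; logits are negated
    Euclidean distances, z-scored across classes then softmaxed, so the
    argmax is the nearest prototype.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")

    def probs(items: Sequence[str], protos: np.ndarray) -> np.ndarray:
        x = np.vstack([np.asarray(vectors[it], dtype=float) for it in items])
        d = np.linalg.norm(x[:, None, :] - protos[None, :, :], axis=2)
        return _softmax_rows(_zscore_rows(-d) / temperature)

    def prototypes(ep: Episode, exclude: str | None = None) -> np.ndarray:
        protos = []
        for ci in range(ep.n_way):
            vecs = [
                np.asarray(vectors[it], dtype=float)
                for it, c in ep.support
                if c == ci and it != exclude
            ]
            protos.append(np.mean(vecs, axis=0))
        return np.vstack(protos)

    def predict(ep: Episode):
        protos = prototypes(ep)
        sup = probs([it for it, _ in ep.support], protos)
        qry = probs([it for it, _ in ep.query], protos)
        return sup, qry

    def support_loo(ep: Episode) -> np.ndarray:
        rows = []
        for it, _ in ep.support:
            rows.append(probs([it], prototypes(ep, exclude=it))[0])
        return np.vstack(rows)

    return _Branch(predict, support_loo)


def bdc_image_branch(
    feature_maps: Mapping[str, FeatureMap] | Callable[[str], FeatureMap],
    axis: str = "channel",
    scale_mode: str = "zscore",
    temperature: float = 1.0,
) -> _Branch:
    """BDC trace-similarity classifier over backbone feature maps.

    Each item's feature map is pooled into its BDC matrix; class prototypes
    are element-wise means of support matrices and queries are scored by
    the Frobenius inner product.  BDC matrices are cached per item.
    """
    getter = feature_maps.__getitem__ if isinstance(feature_maps, Mapping) else feature_maps
    cache: dict[str, BDCMatrix] = {}

    def rep(item: str) -> BDCMatrix:
        if item not in cache:
            cache[item] = bdc_representation(getter(item), axis=axis)
        return cache[item]

    def prototypes(ep: Episode, exclude: str | None = None) -> list[ClassPrototype]:
        out = []
        for ci in range(ep.n_way):
            mats = [rep(it) for it, c in ep.support if c == ci and it != exclude]
            out.append(class_prototype(mats, class_id=ep.class_ids[ci]))
        return out

    def probs(items: Sequence[str], protos: list[ClassPrototype]) -> np.ndarray:
        return np.vstack(
            [
                image_branch_probabilities(
                    rep(it), protos, scale_mode=scale_mode, temperature=temperature
                )
                for it in items
            ]
        )

    def predict(ep: Episode):
        protos = prototypes(ep)
        sup = probs([it for it, _ in ep.support], protos)
        qry = probs([it for it, _ in ep.query], protos)
        return sup, qry

    def support_loo(ep: Episode) -> np.ndarray:
        rows = []
        for it, _ in ep.support:
            rows.append(probs([it], prototypes(ep, exclude=it))[0])
        return np.vstack(rows)

    return _Branch(predict, support_loo)


def text_branch(
    lib: PromptLibrary,
    enc: EncoderPair,
    cfg: TextBranchConfig = TextBranchConfig(),
) -> _Branch:
    """Zero-shot semantic branch: encoder image embedding vs. class prompts.

    The class text matrix is rebuilt per episode from the episode's own
    classes, in episode class order.
    """

    def predict(ep: Episode):
        class_matrix = encode_class_prompts(lib, enc, list(ep.class_ids))

        def probs(items: Sequence[str]) -> np.ndarray:
            return np.vstack(
                [
                    text_branch_probabilities(enc.image_encode(it), class_matrix, cfg)
                    for it in items
                ]
            )

        return probs([it for it, _ in ep.support]), probs([it for it, _ in ep.query])

    return _Branch(predict)
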