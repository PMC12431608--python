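"""Seeded synthetic fixtures with the statistical structure each stage assumes.

Four generators make the whole pipeline testable without any dataset or
pretrained encoder:

* ``gen_embedding_episode`` — class-conditional Gaussian embedding clusters.
  Class means sit at the vertices of a regular simplex a controllable
  ``separation`` apart; items add isotropic noise.  A synthetic paired
  encoder maps each class's compound prompt to a text vector whose
  ``text_fidelity`` interpolates between the true class direction and a
  random unit vector, and maps items to an independently-noised "CLIP-side"
  image embedding.
* ``gen_feature_map_episode`` — backbone-style feature maps whose class
  identity is carried *only* by channel covariance (means are zero), so
  first-order pooling is uninformative but BDC pooling carries signal.
* ``gen_image_set`` — small geometric-pattern images with controllable
  color/position jitter, for the variability statistics.
* ``gen_prompt_library`` — deterministic templated prompt libraries in the
  same JSON layout real libraries use.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .bdc import FeatureMap
from .branches import embedding_prototype_branch, text_branch
from .episodes import Episode, EpisodeTask
from .prompts import (
    ClassPromptSet,
    EncoderPair,
    PromptLibrary,
    TextBranchConfig,
    build_compound_prompt,
)
from .variability import ClassImageSet

__all__ = [
    "EmbeddingTaskSpec",
    "FeatureMapTaskSpec",
    "SyntheticEmbeddingEpisode",
    "SyntheticFeatureMapEpisode",
    "gen_embedding_episode",
    "gen_feature_map_episode",
    "gen_image_set",
    "gen_prompt_library",
    "embedding_task",
    "embedding_task_stream",
    "fidelity_response_stream",
    "complementary_task_stream",
]


@dataclass(frozen=True)
class EmbeddingTaskSpec:
    """Conditions for one synthetic embedding episode.

    ``separation`` is the exact Euclidean distance between any two class
    means; ``noise_sd`` the per-coordinate noise of the metric-branch
    vectors; ``clip_noise_sd`` the (independent) noise of the encoder-side
    image embeddings, defaulting to ``noise_sd``; ``text_fidelity`` in
    [0, 1] dials the text encoder from pure noise (0) to the true class
    direction (1).
    """

    n_way: int = 5
    k_shot: int = 1
    q: int = 2
    dim: int = 16
    separation: float = 0.0
    noise_sd: float = 1.0
    text_fidelity: float = 1.0
    clip_noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_way < 2 or self.dim < 2 or self.k_shot < 1 or self.q < 1:
            raise ValueError("need n_way >= 2, dim >= 2, k_shot >= 1, q >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not 0.0 <= self.text_fidelity <= 1.0:
            raise ValueError("text_fidelity must lie in [0, 1]")
        if self.n_way > self.dim + 1:
            raise ValueError(
                f"cannot place {self.n_way} mutually equidistant means in "
                f"{self.dim} dimensions (max dim + 1)"
            )


@dataclass(frozen=True)
class FeatureMapTaskSpec:
    """Conditions for one synthetic feature-map episode.

    ``covariance_strength`` scales how far each class's channel covariance
    departs from the identity; at 0 every class shares the same isotropic
    law and no classifier can beat chance.
    """

    n_way: int = 5
    k_shot: int = 5
    q: int = 2
    h: int = 6
    w: int = 6
    d: int = 8
    covariance_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h * self.w < 2 or self.d < 2:
            raise ValueError("need h*w >= 2 and d >= 2")
        if self.n_way < 2 or self.k_shot < 1 or self.q < 1:
            raise ValueError("need n_way >= 2, k_shot >= 1, q >= 1")
        if self.covariance_strength < 0:
            raise ValueError("covariance_strength must be non-negative")


def _simplex_means(n: int, dim: int, separation: float) -> np.ndarray:
    """n mutually equidistant points in R^dim, pairwise distance = separation."""
    s = separation / np.sqrt(2.0)
    means = np.zeros((n, dim))
    for i in range(min(n, dim)):
        means[i, i] = s
    if n == dim + 1:
        # the extra vertex on the diagonal: ||a*1 - s*e_i|| = s*sqrt(2)
        a = s * (1.0 + np.sqrt(1.0 + dim)) / dim
        means[dim] = a
    return means


def _class_names(n: int) -> list[str]:
    return [f"Synthetica_Fixturaceae_Classus specimen{i:02d}" for i in range(n)]


def _layout_episode(n_way: int, k_shot: int, q: int, class_names: Sequence[str]) -> Episode:
    support, query = [], []
    for ci in range(n_way):
        for j in range(k_shot):
            support.append((f"c{ci:02d}_s{j:02d}", ci))
        for j in range(q):
            query.append((f"c{ci:02d}_q{j:02d}", ci))
    return Episode(
        n_way=n_way,
        k_shot=k_shot,
        q=q,
        class_ids=tuple(class_names),
        support=tuple(support),
        query=tuple(query),
    )


def _hash_unit(text: str, dim: int) -> np.ndarray:
    """Deterministic pseudo-random unit vector for an unknown string."""
    h = np.frombuffer(text.encode("utf-8"), dtype=np.uint8)
    rng = np.random.default_rng(int(h.sum()) * 2654435761 % (2**31))
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SyntheticEmbeddingEpisode:
    """An episode plus everything the two branches need to run on it."""

    spec: EmbeddingTaskSpec
    episode: Episode
    vectors: dict[str, np.ndarray]
    clip_vectors: dict[str, np.ndarray]
    encoder: EncoderPair
    library: PromptLibrary
    class_means: np.ndarray


def gen_embedding_episode(spec: EmbeddingTaskSpec) -> SyntheticEmbeddingEpisode:
    """Generate one embedding episode under the given conditions.

    Metric-branch and encoder-side image vectors are drawn with independent
    noise around the same class means, mimicking two different backbones
    looking at the same image.
    """
    rng = np.random.default_rng(spec.seed)
    names = _class_names(spec.n_way)
    episode = _layout_episode(spec.n_way, spec.k_shot, spec.q, names)
    means = _simplex_means(spec.n_way, spec.dim, spec.separation)
    clip_sd = spec.noise_sd if spec.clip_noise_sd is None else spec.clip_noise_sd

    vectors: dict[str, np.ndarray] = {}
    clip_vectors: dict[str, np.ndarray] = {}
    for item, ci in list(episode.support) + list(episode.query):
        vectors[item] = means[ci] + spec.noise_sd * rng.normal(size=spec.dim)
        clip_vectors[item] = means[ci] + clip_sd * rng.normal(size=spec.dim)

    library = gen_prompt_library(names, seed=spec.seed)

    text_vecs: dict[str, np.ndarray] = {}
    for ci, name in enumerate(names):
        u = rng.normal(size=spec.dim)
        u /= np.linalg.norm(u)
        v = spec.text_fidelity * means[ci] + (1.0 - spec.text_fidelity) * u
        n = np.linalg.norm(v)
        text_vecs[build_compound_prompt(library[name])] = (
            v / n if n > 1e-12 else u
        )

    def text_encode(prompt: str) -> np.ndarray:
        if prompt in text_vecs:
            return text_vecs[prompt]
        return _hash_unit(prompt, spec.dim)

    def image_encode(item: str) -> np.ndarray:
        return clip_vectors[item]

    return SyntheticEmbeddingEpisode(
        spec=spec,
        episode=episode,
        vectors=vectors,
        clip_vectors=clip_vectors,
        encoder=EncoderPair(text_encode=text_encode, image_encode=image_encode),
        library=library,
        class_means=means,
    )


@dataclass(frozen=True)
class SyntheticFeatureMapEpisode:
    """An episode whose items are feature maps with class-specific covariance."""

    spec: FeatureMapTaskSpec
    episode: Episode
    feature_maps: dict[str, FeatureMap]


def gen_feature_map_episode(spec: FeatureMapTaskSpec) -> SyntheticFeatureMapEpisode:
    """Feature maps whose spatial observations share a class-dependent
    channel covariance ``I + strength * G G^T / d`` (G random per class) and
    zero mean, so only second-order statistics separate the classes."""
    rng = np.random.default_rng(spec.seed)
    names = _class_names(spec.n_way)
    episode = _layout_episode(spec.n_way, spec.k_shot, spec.q, names)

    chols = []
    for _ in range(spec.n_way):
        g = rng.normal(size=(spec.d, spec.d))
        sigma = np.eye(spec.d) + spec.covariance_strength * (g @ g.T) / spec.d
        chols.append(np.linalg.cholesky(sigma))

    feature_maps: dict[str, FeatureMap] = {}
    for item, ci in list(episode.support) + list(episode.query):
        z = rng.normal(size=(spec.h * spec.w, spec.d))
        x = z @ chols[ci].T
        feature_maps[item] = FeatureMap(
            values=x.reshape(spec.h, spec.w, spec.d), source_id=item
        )
    return SyntheticFeatureMapEpisode(spec=spec, episode=episode, feature_maps=feature_maps)


def gen_image_set(
    n_images: int,
    base_pattern: str = "rings",
    jitter_amplitude: float = 0.0,
    seed: int = 0,
    side: int = 48,
) -> ClassImageSet:
    """Images of one geometric pattern with per-image color/position jitter.

    Amplitude 0 yields pixel-identical images; larger amplitudes shift each
    image's channel intensities (uniform in +-amplitude) and translate the
    pattern by up to ``amplitude * side / 2`` pixels.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    if jitter_amplitude < 0:
        raise ValueError("jitter amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side].astype(float) / side

    if base_pattern == "rings":
        r = np.hypot(yy - 0.5, xx - 0.5)
        base = 0.5 + 0.3 * np.cos(12.0 * np.pi * r)
    elif base_pattern == "stripes":
        base = 0.5 + 0.3 * np.sin(10.0 * np.pi * xx)
    elif base_pattern == "checker":
        base = 0.5 + 0.3 * np.sign(np.sin(8 * np.pi * xx) * np.sin(8 * np.pi * yy))
    else:
        raise ValueError(f"unknown base pattern {base_pattern!r}")
    base_rgb = np.stack([base, base, base], axis=-1)

    images = []
    for _ in range(n_images):
        img = base_rgb
        if jitter_amplitude > 0:
            max_shift = jitter_amplitude * side / 2.0
            dy, dx = (rng.uniform(-max_shift, max_shift, size=2)).round().astype(int)
            img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
            offsets = rng.uniform(-jitter_amplitude, jitter_amplitude, size=3)
            img = img + offsets[None, None, :]
        images.append(np.clip(img, 0.0, 1.0))
    return ClassImageSet(class_id=f"{base_pattern}_a{jitter_amplitude:g}", images=images)


_ADJECTIVES = (
    "tall", "dwarf", "woody", "herbaceous", "evergreen", "deciduous",
    "aromatic", "spiny", "glossy", "velvety", "hardy", "trailing",
)
_ORGANS = (
    "leaves", "flowers", "stems", "seed pods", "petals", "rootstocks",
    "bracts", "tendrils",
)
_HABITATS = (
    "alpine meadows", "river banks", "arid steppe", "shaded woodland",
    "coastal dunes", "subtropical valleys",
)


def gen_prompt_library(
    class_names: Sequence[str],
    descriptions_per_class: int = 5,
    seed: int = 0,
    path: str | Path | None = None,
) -> PromptLibrary:
    """Deterministic templated prompt library; optionally written to JSON."""
    if not class_names:
        raise ValueError("need at least one class")
    if descriptions_per_class < 1:
        raise ValueError("need at least one description per class")
    rng = np.random.default_rng(seed)
    entries = {}
    for name in class_names:
        descs = []
        for k in range(descriptions_per_class):
            adj = _ADJECTIVES[rng.integers(len(_ADJECTIVES))]
            organ = _ORGANS[rng.integers(len(_ORGANS))]
            habitat = _HABITATS[rng.integers(len(_HABITATS))]
            descs.append(f"{adj} plant of {name} with distinctive {organ} found in {habitat} ({k})")
        entries[name] = ClassPromptSet(class_name=name, descriptions=tuple(descs))
    lib = PromptLibrary(entries)
    if path is not None:
        from .prompts import save_prompt_library

        save_prompt_library(lib, path)
    return lib


def embedding_task(
    spec: EmbeddingTaskSpec, text_cfg: TextBranchConfig = TextBranchConfig()
) -> EpisodeTask:
    """Wire one synthetic embedding episode to its two branches."""
    se = gen_embedding_episode(spec)
    ib = embedding_prototype_branch(se.vectors)
    tb = text_branch(se.library, se.encoder, text_cfg)
    return se.episode, ib, tb


def embedding_task_stream(
    spec: EmbeddingTaskSpec,
    n_episodes: int,
    seed: int,
    text_cfg: TextBranchConfig = TextBranchConfig(),
) -> list[EpisodeTask]:
    """n independent episodes under one condition, child-seeded from ``seed``."""
    seeds = np.random.SeedSequence(seed).generate_state(n_episodes) % (2**31)
    return [
        embedding_task(replace(spec, seed=int(s)), text_cfg) for s in seeds
    ]


def fidelity_response_stream(
    text_fidelity: float,
    n_episodes: int,
    seed: int,
    text_cfg: TextBranchConfig = TextBranchConfig(),
) -> list[EpisodeTask]:
    """Episodes probing how fusion weights respond to text-encoder fidelity.

    Conditions are fixed at a regime where neither branch saturates
    (5-way 5-shot, separation 1.5, metric noise 1.0, encoder-side noise
    0.8), so the text branch's support loss — and hence its fusion weight —
    tracks ``text_fidelity`` instead of flat-lining at 0 or ln N.
    """
    spec = EmbeddingTaskSpec(
        n_way=5, k_shot=5, q=2, dim=16,
        separation=1.5, noise_sd=1.0, clip_noise_sd=0.8,
        text_fidelity=text_fidelity,
    )
    return embedding_task_stream(spec, n_episodes, seed, text_cfg)


def complementary_task_stream(
    n_episodes: int,
    seed: int,
    n_way: int = 5,
    k_shot: int = 5,
    q: int = 2,
    dim: int = 16,
    text_cfg: TextBranchConfig = TextBranchConfig(),
) -> list[EpisodeTask]:
    """Episodes where a random half favors each modality.

    Image-strong episodes have tight visual clusters but a useless text
    encoder; text-strong episodes have diffuse visual clusters but a
    faithful text encoder over clean encoder-side embeddings.  Neither
    single branch nor any fixed weighting is optimal across the stream.
    """
    ss = np.random.SeedSequence(seed)
    coins = np.random.default_rng(ss.generate_state(1)[0] % (2**31)).random(n_episodes) < 0.5
    seeds = ss.generate_state(n_episodes + 1)[1:] % (2**31)
    tasks = []
    for coin, s in zip(coins, seeds):
        if coin:  # image-strong
            spec = EmbeddingTaskSpec(
                n_way=n_way, k_shot=k_shot, q=q, dim=dim,
                separation=6.0, noise_sd=1.0, clip_noise_sd=4.0,
                text_fidelity=0.0, seed=int(s),
            )
        else:  # text-strong
            spec = EmbeddingTaskSpec(
                n_way=n_way, k_shot=k_shot, q=q, dim=dim,
                separation=6.0, noise_sd=4.0, clip_noise_sd=1.0,
                text_fidelity=1.0, seed=int(s),
            )
        tasks.append(embedding_task(spec, text_cfg))
    return tasks
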