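"""Class-aware structured text prompts and the zero-shot semantic branch.

Each class carries an ordered list of short natural-language descriptions
(appearance, habit, usage, ...) stored in a JSON prompt library.  The
descriptions are concatenated with English commas into one compound
sentence per class, encoded by a paired vision-language encoder, and a
query image is scored by cosine similarity between its image embedding and
each class's text embedding, followed by temperature-scaled softmax.

Encoders are pluggable: any pair of callables mapping text -> vector and
item -> vector of a common length works.  Embeddings are L2-normalized
here, so plug-ins need not guarantee unit norm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ClassPromptSet",
    "PromptLibrary",
    "EncoderPair",
    "TextBranchConfig",
    "load_prompt_library",
    "save_prompt_library",
    "build_compound_prompt",
    "encode_class_prompts",
    "text_branch_probabilities",
]


class PromptSchemaError(ValueError):
    """The prompt library file violates the expected JSON schema."""


@dataclass(frozen=True)
class ClassPromptSet:
    """Ordered textual descriptions for one class (five in typical use)."""

    class_name: str
    descriptions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.class_name:
            raise PromptSchemaError("class name must be non-empty")
        descs = tuple(self.descriptions)
        if not descs:
            raise PromptSchemaError(f"class {self.class_name!r} has no descriptions")
        for d in descs:
            if not isinstance(d, str) or not d:
                raise PromptSchemaError(
                    f"class {self.class_name!r} has an empty or non-string description"
                )
            if "\n" in d or "\r" in d:
                raise PromptSchemaError(
                    f"class {self.class_name!r}: descriptions must not contain line breaks"
                )
        object.__setattr__(self, "descriptions", descs)


@dataclass(frozen=True)
class PromptLibrary:
    """Mapping from class name to its prompt set."""

    entries: Mapping[str, ClassPromptSet]

    def __post_init__(self) -> None:
        if not self.entries:
            raise PromptSchemaError("prompt library is empty")
        object.__setattr__(self, "entries", dict(self.entries))

    def __getitem__(self, class_name: str) -> ClassPromptSet:
        try:
            return self.entries[class_name]
        except KeyError:
            raise KeyError(f"class {class_name!r} not in prompt library") from None

    def __contains__(self, class_name: str) -> bool:
        return class_name in self.entries

    def class_names(self) -> list[str]:
        return list(self.entries)


@dataclass(frozen=True)
class EncoderPair:
    """Paired text/image encoders embedding into one shared space."""

    text_encode: Callable[[str], np.ndarray]
    image_encode: Callable[[object], np.ndarray]


@dataclass(frozen=True)
class TextBranchConfig:
    """Semantic-branch settings.

    ``temperature`` scales cosine similarities before the softmax; the
    default 0.01 matches the usual logit-scale-100 convention of
    vision-language models, under which cosine gaps of a few hundredths
    already produce decisive probabilities.
    """

    temperature: float = 0.01

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def load_prompt_library(path: str | Path) -> PromptLibrary:
    """Load and validate a JSON prompt library (class name -> list of strings)."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise PromptSchemaError("prompt library must be a JSON object")
    entries = {}
    for name, descs in raw.items():
        if not isinstance(descs, list):
            raise PromptSchemaError(f"class {name!r}: descriptions must be a JSON array")
        entries[name] = ClassPromptSet(class_name=name, descriptions=tuple(descs))
    return PromptLibrary(entries)


def save_prompt_library(lib: PromptLibrary, path: str | Path) -> None:
    """Write the library back in the same JSON layout it is loaded from."""
    payload = {name: list(ps.descriptions) for name, ps in lib.entries.items()}
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8")


def build_compound_prompt(ps: ClassPromptSet) -> str:
    """Join the class's descriptions with ", " into one compound sentence.

    No template prefix is added; any trailing punctuation is carried by the
    last description itself.
    """
    return ", ".join(ps.descriptions)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("encoder produced non-finite embedding")
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero-norm embedding")
    return v / n


def encode_class_prompts(
    lib: PromptLibrary, enc: EncoderPair, classes: Sequence[str]
) -> np.ndarray:
    """Encode each class's compound prompt; rows are unit vectors in `classes` order."""
    rows = []
    for name in classes:
        prompt = build_compound_prompt(lib[name])
        rows.append(_unit(enc.text_encode(prompt)))
    mat = np.vstack(rows)
    return mat


def text_branch_probabilities(
    image_vec: np.ndarray,
    class_matrix: np.ndarray,
    cfg: TextBranchConfig = TextBranchConfig(),
) -> np.ndarray:
    """Softmax over cosine(image, class text) / temperature.

    Invariant to positive rescaling of the raw image embedding, since it is
    normalized before the cosine.
    """
    img = _unit(image_vec)
    cm = np.asarray(class_matrix, dtype=float)
    if cm.ndim != 2 or cm.shape[1] != img.size:
        raise ValueError(
            f"class matrix shape {cm.shape} incompatible with image embedding of length {img.size}"
        )
    norms = np.linalg.norm(cm, axis=1)
    if np.any(norms == 0):
        raise ValueError("class matrix contains a zero row")
    cosines = (cm / norms[:, None]) @ img
    logits = cosines / cfg.temperature
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()
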