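import numpy as np
import pytest

from bdcc.episodes import DatasetIndex


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_index(n_classes: int, images_per_class) -> DatasetIndex:
    """In-memory dataset index; images_per_class is an int or per-class list."""
    if isinstance(images_per_class, int):
        images_per_class = [images_per_class] * n_classes
    classes = {}
    for i, count in zip(range(n_classes), images_per_class):
        cid = f"class{i:03d}"
        items = tuple(f"{cid}/Phylum_Family_Genus sp{i:03d}__{j}.png" for j in range(count))
        classes[cid] = (None, items)
    return DatasetIndex(classes)


@pytest.fixture
def small_index():
    return make_index(20, 8)
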