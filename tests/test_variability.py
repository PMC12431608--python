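"""Intra-class variability statistics, normalization and dataset ranking."""

import numpy as np
import pytest
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from bdcc.synthetic import gen_image_set
from bdcc.variability import (
    METRIC_NAMES,
    ClassImageSet,
    InsufficientImagesError,
    MetricVector,
    VariabilityConfig,
    compute_dataset_metrics,
    dataset_variability_report,
    normalize_metrics,
    overall_dissimilarity,
    pairwise_image_metrics,
    rank_datasets,
)

CFG = VariabilityConfig(resize=32, pairs_cap=200, seed=0)


def naive_pairwise(images, cfg):
    """Independent per-pair loop over the four pairwise statistics."""
    from bdcc.variability import _gray  # same preprocessing, independent loop

    grays = [_gray(im, cfg.resize) for im in images]
    embeds = [g.ravel() for g in grays]
    eu, co, ss, ps = [], [], [], []
    n = len(images)
    for i in range(n):
        for j in range(i + 1, n):
            eu.append(np.sqrt(np.sum((embeds[i] - embeds[j]) ** 2)))
            ni, nj = np.linalg.norm(embeds[i]), np.linalg.norm(embeds[j])
            co.append(1.0 - float(embeds[i] @ embeds[j]) / (ni * nj))
            ss.append(structural_similarity(grays[i], grays[j], data_range=1.0))
            mse = np.mean((grays[i] - grays[j]) ** 2)
            ps.append(
                cfg.psnr_cap
                if mse == 0
                else min(peak_signal_noise_ratio(grays[i], grays[j], data_range=1.0), cfg.psnr_cap)
            )
    return map(np.mean, (eu, co, ss, ps))


class TestPairwiseMetrics:
    def test_identical_images(self, rng):
        im = rng.random((16, 16, 3))
        mv = pairwise_image_metrics(ClassImageSet("x", [im, im.copy()]), config=CFG)
        assert mv.avg_euclidean == 0.0
        assert mv.avg_cosine == pytest.approx(0.0, abs=1e-12)
        assert mv.avg_ssim == pytest.approx(1.0)
        assert mv.avg_psnr == CFG.psnr_cap

    def test_uniform_single_color_images(self):
        im = np.full((16, 16, 3), 0.4)
        mv = pairwise_image_metrics(ClassImageSet("x", [im, im.copy()]), config=CFG)
        assert mv.avg_variance == pytest.approx(0.0, abs=1e-15)
        assert mv.avg_color_std == pytest.approx(0.0, abs=1e-15)

    def test_matches_naive_loop(self, rng):
        images = [rng.random((8, 8, 3)) for _ in range(6)]
        cfg = VariabilityConfig(resize=8, pairs_cap=200, seed=0)
        mv = pairwise_image_metrics(ClassImageSet("x", images), config=cfg)
        eu, co, ss, ps = naive_pairwise(images, cfg)
        assert mv.avg_euclidean == pytest.approx(eu, abs=1e-9)
        assert mv.avg_cosine == pytest.approx(co, abs=1e-9)
        assert mv.avg_ssim == pytest.approx(ss, abs=1e-9)
        assert mv.avg_psnr == pytest.approx(ps, abs=1e-9)

    def test_order_invariance(self, rng):
        images = [rng.random((8, 8, 3)) for _ in range(5)]
        cfg = VariabilityConfig(resize=8, pairs_cap=200, seed=0)
        a = pairwise_image_metrics(ClassImageSet("x", images), config=cfg)
        b = pairwise_image_metrics(ClassImageSet("x", images[::-1]), config=cfg)
        np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-9)

    def test_pair_cap_subsampling_deterministic(self, rng):
        images = [rng.random((8, 8, 3)) for _ in range(10)]  # 45 pairs
        cfg = VariabilityConfig(resize=8, pairs_cap=10, seed=3)
        a = pairwise_image_metrics(ClassImageSet("x", images), config=cfg)
        b = pairwise_image_metrics(ClassImageSet("x", images), config=cfg)
        assert a == b

    def test_single_image_rejected(self, rng):
        with pytest.raises(InsufficientImagesError):
            pairwise_image_metrics(ClassImageSet("x", [rng.random((8, 8, 3))]), config=CFG)


class TestJitterMonotonicity:
    def test_color_std_euclidean_up_ssim_down(self):
        amplitudes = (0.05, 0.15, 0.35)
        mvs = [
            pairwise_image_metrics(
                gen_image_set(8, jitter_amplitude=a, seed=11), config=CFG
            )
            for a in amplitudes
        ]
        color = [m.avg_color_std for m in mvs]
        eucl = [m.avg_euclidean for m in mvs]
        ssim = [m.avg_ssim for m in mvs]
        assert color[0] < color[1] < color[2]
        assert eucl[0] < eucl[1] < eucl[2]
        assert ssim[0] > ssim[1] > ssim[2]


class TestNormalizationAndRanking:
    def _raw(self):
        return [
            MetricVector(1.0, 0.2, 0.1, 0.9, 40.0, 0.05),
            MetricVector(3.0, 0.6, 0.1, 0.5, 20.0, 0.20),
            MetricVector(2.0, 0.4, 0.1, 0.7, 30.0, 0.10),
        ]

    def test_minmax_endpoints_and_inversion(self):
        norm = normalize_metrics(self._raw())
        k_eu = METRIC_NAMES.index("avg_euclidean")
        k_ssim = METRIC_NAMES.index("avg_ssim")
        assert norm[1][k_eu] == 1.0  # maximal euclidean -> 1
        assert norm[0][k_ssim] == 0.0  # maximal ssim -> 0 after inversion

    def test_constant_column_maps_to_half(self):
        norm = normalize_metrics(self._raw())
        k = METRIC_NAMES.index("avg_variance")
        assert all(v[k] == 0.5 for v in norm)

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            normalize_metrics([self._raw()[0]])

    def test_overall_score_is_mean(self):
        assert overall_dissimilarity(np.array([1, 1, 1, 0, 0, 0.0])) == 0.5
        assert overall_dissimilarity(np.ones(6)) == 1.0

    def test_rank_descending_with_name_ties(self):
        order = rank_datasets({"b": 0.3, "a": 0.3, "c": 0.9})
        assert order == ["c", "a", "b"]

    def test_duplicating_a_dataset_keeps_relative_order(self):
        jitters = {"lo": 0.05, "mid": 0.2, "hi": 0.4}
        sets = {
            name: [gen_image_set(6, jitter_amplitude=a, seed=7)]
            for name, a in jitters.items()
        }
        df1 = dataset_variability_report(sets, config=CFG)
        sets["mid2"] = sets["mid"]
        df2 = dataset_variability_report(sets, config=CFG)
        order1 = [n for n in df1["dataset"] if n != "mid2"]
        order2 = [n for n in df2["dataset"] if n != "mid2"]
        assert order1 == order2

    def test_report_ranks_jitter_levels(self):
        sets = {
            name: [gen_image_set(6, jitter_amplitude=a, seed=7)]
            for name, a in [("lo", 0.05), ("hi", 0.4)]
        }
        df = dataset_variability_report(sets, config=CFG)
        assert df.iloc[0]["dataset"] == "hi"
        assert df["rank"].tolist() == [1, 2]


class TestDatasetLevel:
    def test_mean_over_classes(self, rng):
        a = ClassImageSet("a", [rng.random((8, 8, 3)) for _ in range(3)])
        b = ClassImageSet("b", [rng.random((8, 8, 3)) for _ in range(3)])
        cfg = VariabilityConfig(resize=8, pairs_cap=200, seed=0)
        mv = compute_dataset_metrics([a, b], config=cfg)
        va = pairwise_image_metrics(a, config=cfg).as_array()
        vb = pairwise_image_metrics(b, config=cfg).as_array()
        np.testing.assert_allclose(mv.as_array(), (va + vb) / 2, atol=1e-12)

    def test_disk_round_trip(self, tmp_path):
        import imageio.v3 as iio

        from bdcc.variability import load_dataset

        for ci, a in enumerate([0.1, 0.3]):
            cs = gen_image_set(3, jitter_amplitude=a, seed=ci)
            d = tmp_path / f"class{ci}"
            d.mkdir()
            for j, im in enumerate(cs.images):
                iio.imwrite(d / f"im{j}.png", (im * 255).astype(np.uint8))
        sets = load_dataset(tmp_path)
        assert [cs.class_id for cs in sets] == ["class0", "class1"]
        mv = compute_dataset_metrics(sets, config=CFG)
        assert np.isfinite(mv.as_array()).all()
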