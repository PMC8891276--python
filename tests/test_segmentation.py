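"""Feature banks, forest training, probability maps, labeling."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from noisescore.exceptions import InsufficientDataError
from noisescore.replicas import RawImage
from noisescore.segmentation import (AnnotationSet, FeatureBank,
                                     compute_features, label_objects,
                                     predict_probability, threshold_mask,
                                     train_classifier, upsample_for_model)
from noisescore.codecs import reduce_bit_depth, noise_preserving_compress


@pytest.fixture(scope="module")
def two_level():
    """Deterministic two-level phantom: bright square on dark field."""
    img = np.full((64, 64), 1000, dtype=np.float64)
    img[20:44, 20:44] = 5000
    return img


@pytest.fixture(scope="module")
def two_level_training(two_level):
    bank = FeatureBank.default_2d()
    feats, _ = compute_features(two_level, bank)
    labels = np.zeros(two_level.shape, dtype=np.uint8)
    labels[:8, :8] = 1          # background scribble
    labels[28:36, 28:36] = 2    # foreground scribble
    ann = AnnotationSet(labels, ("background", "cell"))
    clf = train_classifier(feats, ann, seed=0)
    return bank, feats, ann, clf


class TestComputeFeatures:
    def test_constant_image_has_zero_gradients(self):
        bank = FeatureBank.default_2d()
        feats, names = compute_features(np.full((32, 32), 7.0), bank)
        for i, name in enumerate(names):
            if name.startswith(("sobel", "DoG")):
                assert np.allclose(feats[..., i], 0), name

    def test_gaussian_smoothing_preserves_mass(self):
        impulse = np.zeros((33, 33))
        impulse[16, 16] = 1.0
        bank = FeatureBank(("gaussian_smoothing",), (2.0,), 2)
        feats, names = compute_features(impulse, bank)
        assert feats[..., names.index("GS_s2")].sum() == pytest.approx(1.0)

    def test_dog_zero_crossing_matches_dense_convolution(self):
        """DoG(s, 2s) of a Gaussian blob changes sign at the radius the
        brute-force direct convolution predicts, within 1 pixel."""
        y, x = np.mgrid[0:64, 0:64]
        blob = np.exp(-((y - 32.0) ** 2 + (x - 32.0) ** 2) / (2 * 36.0))
        s = 2.0
        bank = FeatureBank(("difference_of_gaussians",), (s,), 2)
        feats, names = compute_features(blob, bank)
        dog = feats[32, 32:, names.index("DoG_s2")]

        def dense_gauss(img, sigma):
            r = np.arange(-24, 25)
            k = np.exp(-r[:, None] ** 2 / (2 * sigma ** 2)) * \
                np.exp(-r[None, :] ** 2 / (2 * sigma ** 2))
            k /= k.sum()
            return ndi.convolve(img, k, mode="reflect")

        oracle = (dense_gauss(blob, s) - dense_gauss(blob, 2 * s))[32, 32:]
        r_impl = np.argmax(dog < 0)
        r_oracle = np.argmax(oracle < 0)
        assert abs(int(r_impl) - int(r_oracle)) <= 1

    def test_oversized_sigma_skipped_with_warning(self):
        bank = FeatureBank(("gaussian_smoothing",), (1.0, 50.0), 2)
        with pytest.warns(UserWarning):
            feats, names = compute_features(np.zeros((32, 32)), bank)
        assert names == ["raw", "GS_s1"]

    def test_dimensionality_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_features(np.zeros((8, 8, 8)), FeatureBank.default_2d())

    def test_hessian_contributes_two_planes_2d(self):
        bank = FeatureBank(("hessian",), (2.0,), 2)
        _, names = compute_features(np.zeros((16, 16)), bank)
        assert names == ["raw", "hessian_e0_s2", "hessian_e1_s2"]


class TestTrainPredict:
    def test_separable_phantom_trains_to_perfection(self, two_level_training):
        _, feats, ann, clf = two_level_training
        mask = ann.labels > 0
        acc = clf.forest.score(feats[mask], ann.labels[mask])
        assert acc == 1.0

    def test_default_forest_configuration_2d(self, two_level_training):
        _, _, _, clf = two_level_training
        assert clf.forest.n_estimators == 200
        assert clf.forest.max_features == 2

    def test_prediction_deterministic(self, two_level_training):
        _, feats, _, clf = two_level_training
        a = predict_probability(clf, feats).probabilities
        b = predict_probability(clf, feats).probabilities
        assert np.array_equal(a, b)

    def test_probabilities_sum_to_one(self, two_level_training):
        _, feats, _, clf = two_level_training
        probs = predict_probability(clf, feats).probabilities
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_annotated_pixels_recover_their_class(self, two_level_training):
        _, feats, ann, clf = two_level_training
        probs = predict_probability(clf, feats)
        fg = probs.for_class("cell")
        assert fg[ann.labels == 2].min() > 0.5
        assert fg[ann.labels == 1].max() < 0.5

    def test_missing_class_rejected(self):
        labels = np.zeros((8, 8), dtype=np.uint8)
        labels[0, 0] = 1
        with pytest.raises(InsufficientDataError):
            AnnotationSet(labels, ("background", "cell"))

    def test_feature_count_mismatch_rejected(self, two_level_training):
        _, feats, _, clf = two_level_training
        with pytest.raises(ValueError):
            predict_probability(clf, feats[..., :3])


class TestThresholdMask:
    def test_full_probability_gives_full_mask(self, two_level_training):
        _, feats, _, clf = two_level_training
        probs = predict_probability(clf, feats)
        probs.probabilities[..., 1] = 1.0
        assert threshold_mask(probs, "cell", 0.5).all()

    def test_strict_inequality_at_threshold(self, two_level_training):
        _, feats, _, clf = two_level_training
        probs = predict_probability(clf, feats)
        probs.probabilities[..., 1] = 0.5
        assert not threshold_mask(probs, "cell", 0.5).any()

    def test_raising_threshold_never_grows_mask(self, two_level_training):
        _, feats, _, clf = two_level_training
        probs = predict_probability(clf, feats)
        lo = threshold_mask(probs, "cell", 0.5)
        hi = threshold_mask(probs, "cell", 0.7)
        assert not (hi & ~lo).any()

    def test_unknown_class_rejected(self, two_level_training):
        _, feats, _, clf = two_level_training
        probs = predict_probability(clf, feats)
        with pytest.raises(KeyError):
            threshold_mask(probs, "mitochondria", 0.5)


def _flood_fill_count(mask: np.ndarray) -> int:
    """Brute-force 8-connected component count (oracle)."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and \
                                    mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
    return count


class TestLabelObjects:
    def test_single_disk_single_label(self):
        y, x = np.mgrid[0:32, 0:32]
        mask = (y - 16) ** 2 + (x - 16) ** 2 <= 36
        assert label_objects(mask).n_objects == 1

    def test_diagonal_touch_is_one_object_2d(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_objects(mask).n_objects == 1

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            mask = rng.random((32, 32)) < 0.35
            assert label_objects(mask).n_objects == _flood_fill_count(mask)


class TestUpsampleForModel:
    def test_exact_multiple_roundtrip(self):
        img = RawImage(np.full((8, 8), 256, dtype=np.uint16))
        out = upsample_for_model(reduce_bit_depth(img))
        assert np.all(out.pixels == 256)

    def test_always_sixteen_bit(self, model, flat_image):
        raw = RawImage(flat_image)
        for variant in (reduce_bit_depth(raw),
                        noise_preserving_compress(raw, model, seed=0)):
            assert upsample_for_model(variant).pixels.dtype == np.uint16

    def test_noise_preserving_passes_through(self, model, flat_image):
        raw = RawImage(flat_image)
        v = noise_preserving_compress(raw, model, seed=0)
        assert np.array_equal(upsample_for_model(v).pixels, v.decoded_16bit)
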