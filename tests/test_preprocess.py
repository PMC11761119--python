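"""Kernel-isolation and augmentation pipeline contracts."""

import numpy as np
import pytest

from grainqc import fixtures as fx
from grainqc import preprocess as pp

from conftest import gray_mean, solidity


# --------------------------------------------------------------------------
# grayscale / denoise / threshold
# --------------------------------------------------------------------------

class TestGrayscale:
    def test_constant_image_invariant(self):
        img = np.full((8, 8, 3), 77, dtype=np.uint8)
        np.testing.assert_allclose(pp.to_grayscale(img), 77.0)

    def test_green_brighter_than_red(self):
        red = np.zeros((1, 1, 3)); red[..., 0] = 200
        green = np.zeros((1, 1, 3)); green[..., 1] = 200
        assert pp.to_grayscale(green) > pp.to_grayscale(red)

    def test_luminance_weights(self):
        # direct evaluation of the Rec.601 combination
        px = np.array([[[100, 50, 200]]], dtype=float)
        expect = 0.299 * 100 + 0.587 * 50 + 0.114 * 200
        assert abs(pp.to_grayscale(px)[0, 0] - expect) < 1e-9

    def test_gray_passthrough(self):
        g = np.arange(16, dtype=float).reshape(4, 4)
        np.testing.assert_array_equal(pp.to_grayscale(g), g)

    def test_wrong_channels_rejected(self):
        with pytest.raises(ValueError):
            pp.to_grayscale(np.zeros((4, 4, 4)))


class TestGaussianDenoise:
    def test_constant_preserved(self):
        img = np.full((16, 16), 42.0)
        np.testing.assert_allclose(pp.gaussian_denoise(img, 1.0), 42.0)

    def test_impulse_center_weight_matches_kernel(self):
        # explicit discrete-kernel oracle: centre value of a filtered
        # impulse equals the kernel's centre weight
        sigma, radius = 1.0, 3
        xs = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (xs / sigma) ** 2)
        k1 /= k1.sum()
        center_weight = k1[radius] ** 2  # separable 2-D kernel
        img = np.zeros((15, 15))
        img[7, 7] = 100.0
        out = pp.gaussian_denoise(img, sigma)
        assert abs(out[7, 7] - 100.0 * center_weight) < 1e-6

    def test_noise_variance_decreases(self):
        noise = np.random.default_rng(0).normal(100, 10, size=(64, 64))
        assert pp.gaussian_denoise(noise, 1.0).var() < noise.var()

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            pp.gaussian_denoise(np.zeros((4, 4)), 0.0)


def otsu_bruteforce(gray: np.ndarray) -> int:
    """Maximise between-class variance over all 256 integer thresholds."""
    best_t, best_v = 0, -1.0
    g = gray.reshape(-1)
    for t in range(256):
        lo, hi = g[g < t], g[g >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / g.size, hi.size / g.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


class TestBinarize:
    def test_otsu_separates_two_levels(self):
        rng = np.random.default_rng(1)
        gray = np.where(rng.random((32, 32)) < 0.3, 50.0, 200.0)
        mask = pp.binarize(gray, "otsu")
        t_oracle = otsu_bruteforce(gray)
        assert 50 < t_oracle <= 200
        np.testing.assert_array_equal(mask.pixels, gray < t_oracle
                                      if mask.polarity == "foreground_low"
                                      else gray >= t_oracle)
        # the 30% side must be foreground
        assert mask.pixels.mean() == pytest.approx(0.3, abs=0.05)

    def test_fixed_threshold(self):
        gray = np.where(np.eye(8, dtype=bool), 200.0, 30.0)
        mask = pp.binarize(gray, "fixed", threshold=128)
        np.testing.assert_array_equal(mask.pixels, gray >= 128)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            pp.binarize(np.full((8, 8), 9.0), "otsu")

    def test_fixed_requires_threshold(self):
        with pytest.raises(ValueError):
            pp.binarize(np.zeros((4, 4)), "fixed")


# --------------------------------------------------------------------------
# contours + crops + full segmentation
# --------------------------------------------------------------------------

class TestContours:
    def test_empty_mask(self):
        mask = pp.BinaryMask(np.zeros((10, 10), dtype=bool), "foreground_high")
        assert pp.extract_contours(mask) == []

    def test_square_centroid_from_moments(self):
        px = np.zeros((64, 64), dtype=bool)
        px[30:40, 20:30] = True  # 10x10 square, x in [20,30), y in [30,40)
        (c,) = pp.extract_contours(pp.BinaryMask(px, "foreground_high"))
        assert c.centroid == pytest.approx((24.5, 34.5))
        assert c.area == 100

    def test_min_area_filters_specks(self):
        px = np.zeros((64, 64), dtype=bool)
        px[10:20, 10:20] = True
        px[40, 40] = True  # 1-px speck
        cs = pp.extract_contours(pp.BinaryMask(px, "foreground_high"), min_area=4)
        assert len(cs) == 1

    def test_tray_centroids_match_ground_truth(self, tray_12):
        gray = pp.gaussian_denoise(pp.to_grayscale(tray_12.pixels), 1.0)
        cs = pp.extract_contours(pp.binarize(gray), min_area=30)
        assert len(cs) == len(tray_12.kernels)
        gt = np.array([k.center for k in tray_12.kernels])
        for c in cs:
            d = np.hypot(gt[:, 0] - c.centroid[0], gt[:, 1] - c.centroid[1]).min()
            assert d <= 2.0


class TestCropMinRect:
    def _rect_contour(self, x0, y0, w, h, angle_deg=0.0):
        corners = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
        ang = np.deg2rad(angle_deg)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        pts = corners @ R.T + [x0, y0]
        return pp.Contour(points=pts, centroid=tuple(pts.mean(0)), area=w * h)

    def test_axis_aligned_rectangle(self):
        img = np.full((64, 64, 3), 200, dtype=np.uint8)
        crop = pp.crop_min_rect(img, self._rect_contour(10, 20, 10, 20), padding=0)
        h, w = crop.image.shape[:2]
        assert abs(w - 10) <= 1 and abs(h - 20) <= 1 or abs(w - 20) <= 1 and abs(h - 10) <= 1

    def test_rotated_rectangle_tighter_than_bbox(self):
        c = self._rect_contour(30, 5, 10, 20, angle_deg=45.0)
        _, w, h, angle = pp._min_area_rect(c.points)
        assert w * h == pytest.approx(200, rel=0.02)  # rotating-calipers oracle
        xs, ys = c.points[:, 0], c.points[:, 1]
        bbox_area = np.ptp(xs) * np.ptp(ys)
        assert w * h < bbox_area

    def test_degenerate_contour_rejected(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            pp.crop_min_rect(img, pp.Contour(np.array([[1.0, 1.0], [2.0, 2.0]]),
                                             (1.5, 1.5), 0.0))

    def test_fixture_crop_contains_kernel(self):
        tray = fx.generate_tray(1, canvas=(128, 128), seed=4)
        crops = pp.segment_kernels(tray.pixels)
        assert len(crops) == 1
        x, y, w, h, _ = crops[0].source_box
        ys, xs = np.nonzero(tray.masks[0])
        # nearly all ground-truth pixels inside the (rotated) source box —
        # conservative check with the box's axis-aligned envelope
        cx, cy = crops[0].centroid
        r = np.hypot(w, h) / 2 + 2
        inside = np.hypot(xs - cx, ys - cy) <= r
        assert inside.mean() >= 0.99


class TestSegmentKernels:
    def test_blank_tray_empty(self):
        blank = np.full((100, 100, 3), 235, dtype=np.uint8)
        assert pp.segment_kernels(blank) == []

    def test_recovers_all_kernels_with_labels(self, tray_12):
        crops = pp.segment_kernels(tray_12.pixels)
        assert len(crops) == 12
        gt = {tuple(np.round(k.center)): k.label for k in tray_12.kernels}
        matched = 0
        for c in crops:
            for (gx, gy), lab in gt.items():
                if np.hypot(c.centroid[0] - gx, c.centroid[1] - gy) <= 2.5:
                    matched += 1
                    break
        assert matched == 12

    def test_row_major_order_and_determinism(self, tray_12):
        a = pp.segment_kernels(tray_12.pixels)
        b = pp.segment_kernels(tray_12.pixels)
        assert [c.centroid for c in a] == [c.centroid for c in b]
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))
        ys = [c.centroid[1] for c in a]
        assert ys == sorted(ys)


# --------------------------------------------------------------------------
# augmentation / balancing / split
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def kernel_img():
    img, _ = fx.generate_kernel(fx.KernelSpec("good", (48.0, 48.0), (18.0, 12.0)),
                                seed=3, canvas=(96, 96))
    return img


class TestAugment:
    def test_zero_salt_pepper_is_identity(self, kernel_img):
        cfg = pp.AugmentationConfig(sp_amount=0.0)
        out = pp.augment_image(kernel_img, "salt_pepper", cfg, seed=1)
        np.testing.assert_array_equal(out, kernel_img)

    def test_rotate_180_involution(self, kernel_img):
        cfg = pp.AugmentationConfig()
        once = pp.augment_image(kernel_img, "rotate_180", cfg, seed=0)
        twice = pp.augment_image(once, "rotate_180", cfg, seed=0)
        np.testing.assert_array_equal(twice, kernel_img)

    def test_salt_pepper_binomial_count(self):
        img = np.full((100, 100, 3), 128, dtype=np.uint8)
        cfg = pp.AugmentationConfig(sp_amount=0.05)
        out = pp.augment_image(img, "salt_pepper", cfg, seed=2)
        altered = (out != img).any(axis=2).sum()
        # 99% binomial interval, n = 10000, p = 0.05
        sd = np.sqrt(10000 * 0.05 * 0.95)
        assert 500 - 2.576 * sd <= altered <= 500 + 2.576 * sd

    def test_deterministic_per_seed(self, kernel_img):
        cfg = pp.AugmentationConfig()
        a = pp.augment_image(kernel_img, "gaussian_noise", cfg, seed=9)
        b = pp.augment_image(kernel_img, "gaussian_noise", cfg, seed=9)
        c = pp.augment_image(kernel_img, "gaussian_noise", cfg, seed=10)
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_unknown_op_rejected(self, kernel_img):
        with pytest.raises(ValueError):
            pp.augment_image(kernel_img, "zoom", pp.AugmentationConfig(), seed=0)

    @pytest.mark.parametrize("op", pp.AUGMENT_OPS)
    def test_label_semantics_survive(self, op):
        """Solidity (broken < good) and intensity (moldy < good) orderings
        survive each augmentation at default ranges."""
        cfg = pp.AugmentationConfig()
        imgs = {}
        for lab, extra in (("good", {}), ("broken", {"notch_fraction": 0.4}),
                           ("moldy", {"blemish_count": 5})):
            spec = fx.KernelSpec(lab, (48.0, 48.0), (18.0, 12.0), angle=20.0, **extra)
            img, _ = fx.generate_kernel(spec, seed=6, canvas=(96, 96))
            aug = pp.augment_image(img, op, cfg, seed=4)
            mask = pp.binarize(pp.gaussian_denoise(pp.to_grayscale(aug), 1.0)).pixels
            from skimage.measure import label as cc_label, regionprops

            lab_img = cc_label(mask)
            big = max(regionprops(lab_img), key=lambda r: r.area)
            comp = lab_img == big.label
            imgs[lab] = (solidity(comp), gray_mean(aug, comp))
        assert imgs["broken"][0] < imgs["good"][0]
        assert imgs["moldy"][1] < imgs["good"][1]


class TestBalanceAndExpand:
    def _dataset(self, counts=(12, 9, 11)):
        data = []
        rng = np.random.default_rng(0)
        for lab, n in zip(fx.LABELS, counts):
            for i in range(n):
                img = rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
                data.append(pp.LabeledImage(image=img, label=lab))
        return data

    def test_counts_reach_target(self):
        out = pp.balance_and_expand(self._dataset(), 20, seed=1)
        labels = [it.label for it in out]
        assert all(labels.count(lab) == 20 for lab in fx.LABELS)

    def test_originals_retained(self):
        data = self._dataset()
        out = pp.balance_and_expand(data, 20, seed=1)
        for orig, new in zip(data, out[: len(data)]):
            assert np.array_equal(orig.image, new.image)
            assert new.provenance == []

    def test_target_at_max_only_augments_smaller(self):
        out = pp.balance_and_expand(self._dataset(), 12, seed=1)
        synth = [it for it in out if it.provenance]
        assert all(it.label in ("moldy", "broken") for it in synth)

    def test_target_below_count_rejected(self):
        with pytest.raises(ValueError):
            pp.balance_and_expand(self._dataset(), 5, seed=1)

    def test_provenance_replays_identically(self):
        data = self._dataset()
        out = pp.balance_and_expand(data, 20, seed=1)
        for it in out:
            if it.provenance:
                replayed = pp.replay_provenance(out, it)
                np.testing.assert_array_equal(replayed, it.image)


class TestSplitDataset:
    def _dataset(self, counts):
        data = []
        for lab, n in zip(fx.LABELS, counts):
            for i in range(n):
                data.append(pp.LabeledImage(image=np.zeros((2, 2, 3), np.uint8),
                                            label=lab))
        return data

    def test_80_20(self):
        train, test = pp.split_dataset(self._dataset((40, 30, 30)),
                                       pp.SplitSpec(0.8, False, 0))
        assert len(train) == 80 and len(test) == 20

    def test_stratified_counts(self):
        train, test = pp.split_dataset(self._dataset((40, 40, 20)),
                                       pp.SplitSpec(0.8, True, 0))
        counts = {lab: sum(1 for it in train if it.label == lab) for lab in fx.LABELS}
        assert counts == {"good": 32, "moldy": 32, "broken": 16}

    def test_disjoint_and_exhaustive(self):
        data = self._dataset((10, 10, 10))
        train, test = pp.split_dataset(data, pp.SplitSpec(0.8, True, 3))
        ids_train = {id(it) for it in train}
        ids_test = {id(it) for it in test}
        assert not ids_train & ids_test
        assert len(ids_train | ids_test) == 30

    def test_single_fixed_split_per_seed(self):
        data = self._dataset((10, 10, 10))
        a = pp.split_dataset(data, pp.SplitSpec(0.8, True, 5))
        b = pp.split_dataset(data, pp.SplitSpec(0.8, True, 5))
        assert [id(x) for x in a[0]] == [id(x) for x in b[0]]

    def test_small_class_rejected(self):
        data = self._dataset((5, 5, 1))
        with pytest.raises(ValueError):
            pp.split_dataset(data, pp.SplitSpec(0.8, True, 0))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            pp.SplitSpec(1.0, True, 0).validate()
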