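"""Multi-task loss, augmentation, dataset splitting and the fit loop."""

import numpy as np
import pytest

from gaitpose.codec import CodecConfig, LabelBundle, encode_bundle
from gaitpose.network import ModelConfig, NetworkOutputs, build_model
from gaitpose.nn import Tensor
from gaitpose.skeleton import DEFAULT_SKELETON, KeypointSet
from gaitpose.training import (AugmentConfig, LossWeights, TrainConfig,
                               augment_sample, fit, grayscale_depth_proxy,
                               multitask_loss, split_dataset)


def _zero_pred(grid=128, full=512):
    z = lambda *s: Tensor(np.zeros(s, np.float32))
    return NetworkOutputs(depth=z(1, 1, full, full),
                          heatmap=z(1, 8, grid, grid),
                          offsets=z(1, 16, grid, grid),
                          jgs=z(1, 8, grid, grid))


def _empty_bundle(grid=128, full=512):
    return LabelBundle(heatmap=np.zeros((8, grid, grid), np.float32),
                       offsets=np.zeros((16, grid, grid), np.float32),
                       offset_mask=np.zeros((8, grid, grid), bool),
                       jgs=np.zeros((8, grid, grid), np.float32),
                       depth=np.zeros((full, full), np.float32))


class TestLoss:
    def test_zero_when_prediction_equals_labels(self, rendered_sequence):
        _, frames, depths, kps = rendered_sequence
        lb = encode_bundle(kps[0], depths[0])
        pred = NetworkOutputs(depth=Tensor(lb.depth[None, None]),
                              heatmap=Tensor(lb.heatmap[None]),
                              offsets=Tensor(lb.offsets[None]),
                              jgs=Tensor(lb.jgs[None]))
        assert multitask_loss(pred, lb).item() == 0.0

    def test_single_heatmap_cell_hand_value(self):
        lb = _empty_bundle()
        lb.heatmap[0, 10, 10] = 1.0
        loss = multitask_loss(_zero_pred(), lb)
        assert loss.item() == pytest.approx(16.0 / 128 ** 2, rel=1e-6)
        assert loss.item() == pytest.approx(9.7656e-4, rel=1e-4)

    def test_linear_in_alpha(self):
        lb = _empty_bundle(32, 128)
        lb.heatmap[0, 3, 3] = 0.7
        lb.depth[5, 5] = 0.2  # contributes to the unweighted depth term
        l1 = multitask_loss(_zero_pred(32, 128), lb, LossWeights(alpha=16)).item()
        l2 = multitask_loss(_zero_pred(32, 128), lb, LossWeights(alpha=32)).item()
        base = multitask_loss(_zero_pred(32, 128), lb, LossWeights(alpha=0)).item()
        assert l2 - base == pytest.approx(2 * (l1 - base), rel=1e-6)

    def test_offset_errors_masked(self):
        lb = _empty_bundle(32, 128)
        pred = _zero_pred(32, 128)
        pred.offsets.data[0, 0, 2, 2] = 0.5  # outside any positive cell
        assert multitask_loss(pred, lb).item() == 0.0
        lb.offset_mask[0, 2, 2] = True
        assert multitask_loss(pred, lb).item() == pytest.approx(
            2 * 0.25 / 128 ** 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multitask_loss(_zero_pred(32, 128), _empty_bundle(64, 256))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1)


class TestAugment:
    CFG_MIRROR = AugmentConfig(occlusion_prob=0.0, rotation_deg=0.0,
                               mirror_prob=1.0)

    def _sample(self, rng):
        img = rng.random((64, 64, 3)).astype(np.float32)
        depth = rng.random((64, 64)).astype(np.float32)
        kp = KeypointSet(rng.integers(5, 59, (8, 2)).astype(float))
        return img, depth, kp

    def test_mirror_twice_restores(self, rng):
        img, depth, kp = self._sample(rng)
        i1, d1, k1 = augment_sample(img, depth, kp, self.CFG_MIRROR, 1)
        i2, d2, k2 = augment_sample(i1, d1, k1, self.CFG_MIRROR, 2)
        np.testing.assert_array_equal(i2, img)
        np.testing.assert_array_equal(k2.coords, kp.coords)

    def test_mirror_coordinates_and_joint_swap(self, rng):
        img = np.zeros((512, 512, 3), np.float32)
        img[7, 100] = 1.0
        kp = KeypointSet(np.tile([100.0, 7.0], (8, 1)))
        im, _, km = augment_sample(img, np.zeros((512, 512), np.float32), kp,
                                   self.CFG_MIRROR, 0)
        assert km.coords[0, 0] == 411.0
        # the pixel moved where the keypoint says it should be
        assert im[7, 411, 0] == 1.0
        perm = DEFAULT_SKELETON.mirror_permutation()
        assert perm[0] == DEFAULT_SKELETON.index("RS")

    def test_zero_rotation_is_identity_on_keypoints(self, rng):
        img, depth, kp = self._sample(rng)
        cfg = AugmentConfig(occlusion_prob=0.0, rotation_deg=0.0,
                            mirror_prob=0.0)
        _, _, k = augment_sample(img, depth, kp, cfg, 3)
        np.testing.assert_array_equal(k.coords, kp.coords)

    def test_rotation_moves_image_feature_with_keypoint(self):
        """Image content and keypoints rotate coherently: the rotated
        keypoint lands on the rotated bright blob (within resampling)."""
        img = np.zeros((128, 128, 3), np.float32)
        img[30:34, 90:94] = 1.0
        kp = KeypointSet(np.tile([91.5, 31.5], (8, 1)))
        cfg = AugmentConfig(occlusion_prob=0.0, rotation_deg=10.0,
                            mirror_prob=0.0)
        im, _, k = augment_sample(img, np.zeros((128, 128), np.float32), kp,
                                  cfg, 11)
        x, y = k.coords[0]
        assert im[int(round(y)), int(round(x)), 0] > 0.25

    def test_occlusion_leaves_labels_and_uses_mean_fill(self, rng):
        img, depth, kp = self._sample(rng)
        cfg = AugmentConfig(occlusion_prob=1.0, rotation_deg=0.0,
                            mirror_prob=0.0)
        im, _, k = augment_sample(img, depth, kp, cfg, 5)
        np.testing.assert_array_equal(k.coords, kp.coords)
        changed = np.argwhere((im != img).any(axis=2))
        assert changed.size > 0
        y0, x0 = changed[0]
        np.testing.assert_allclose(im[y0, x0], img.mean(axis=(0, 1)),
                                   atol=1e-6)

    def test_deterministic_given_seed(self, rng):
        img, depth, kp = self._sample(rng)
        a = augment_sample(img, depth, kp, AugmentConfig(), 42)
        b = augment_sample(img, depth, kp, AugmentConfig(), 42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[2].coords, b[2].coords)

    def test_mirror_commutes_with_encoding(self, rng):
        """Encoding mirrored keypoints equals channel-permuted flipped
        encodings (exact for the heatmap)."""
        from gaitpose.codec import encode_heatmap
        kp = KeypointSet(rng.integers(8, 120, (8, 2)).astype(float))
        mkp = kp.mirrored(128)
        perm = DEFAULT_SKELETON.mirror_permutation()
        h = encode_heatmap(kp, 32, 32)
        hm = encode_heatmap(mkp, 32, 32)
        np.testing.assert_allclose(hm, h[perm][:, :, ::-1], atol=1e-6)


class TestSplit:
    def test_published_corpus_split_sizes(self):
        tr, va = split_dataset(3588, 4, 1, seed=0)
        assert (len(tr), len(va)) == (2870, 718)

    def test_small_split(self):
        tr, va = split_dataset(10, 4, 1, seed=1)
        assert (len(tr), len(va)) == (8, 2)

    @pytest.mark.parametrize("n", [5, 37, 101])
    def test_partition_property(self, n):
        tr, va = split_dataset(n, 4, 1, seed=7)
        assert set(tr) | set(va) == set(range(n))
        assert set(tr) & set(va) == set()

    def test_seed_reproducible(self):
        assert (split_dataset(50, 4, 1, 3)[0] == split_dataset(50, 4, 1, 3)[0]).all()
        assert not (split_dataset(50, 4, 1, 3)[0] == split_dataset(50, 4, 1, 4)[0]).all()

    def test_bad_ratios(self):
        with pytest.raises(ValueError):
            split_dataset(10, 0, 1)


class TestGrayscaleProxy:
    def test_extremes_and_midgray(self):
        white = np.full((4, 4, 3), 255, np.uint8)
        black = np.zeros((4, 4, 3), np.uint8)
        mid = np.full((4, 4, 3), 128, np.uint8)
        assert grayscale_depth_proxy(white).max() == pytest.approx(1.0)
        assert grayscale_depth_proxy(black).max() == 0.0
        assert grayscale_depth_proxy(mid)[0, 0] == pytest.approx(0.50196,
                                                                 abs=1e-5)


class TestFit:
    def _tiny_dataset(self, rendered_sequence, n=8, size=64):
        _, frames, depths, kps = rendered_sequence
        data = []
        for i in range(n):
            img = frames[i, ::2, ::2]  # 128 -> 64
            dep = depths[i, ::2, ::2]
            kp = KeypointSet(kps[i].coords / 2.0, kps[i].visible)
            data.append((img.transpose(2, 0, 1).astype(np.float32),
                         encode_bundle(kp, dep)))
        return data

    def test_loss_decreases_across_seeds(self, rendered_sequence):
        data = self._tiny_dataset(rendered_sequence)
        drops = 0
        for seed in (0, 1, 2):
            model = build_model(ModelConfig(input_size=64,
                                            width_multiplier=0.25, seed=seed))
            hist = fit(model, data, TrainConfig(epochs=5, batch_size=4,
                                                seed=seed))
            drops += hist["loss"][-1] < hist["loss"][0]
        assert drops >= 2

    def test_same_seed_same_trajectory(self, rendered_sequence):
        data = self._tiny_dataset(rendered_sequence, n=4)
        runs = []
        for _ in range(2):
            model = build_model(ModelConfig(input_size=64,
                                            width_multiplier=0.25, seed=5))
            runs.append(fit(model, data, TrainConfig(epochs=3, batch_size=4,
                                                     seed=5))["loss"])
        np.testing.assert_allclose(runs[0], runs[1], rtol=1e-6)

    def test_empty_dataset_rejected(self):
        model = build_model(ModelConfig(input_size=64, width_multiplier=0.25))
        with pytest.raises(ValueError):
            fit(model, [], TrainConfig(epochs=1))

    def test_finetune_freezes_stem(self, rendered_sequence):
        data = self._tiny_dataset(rendered_sequence, n=4)
        model = build_model(ModelConfig(input_size=64, width_multiplier=0.25))
        stem_before = model.stem.weight.data.copy()
        head_before = model.head_heat.out.weight.data.copy()
        fit(model, data, TrainConfig(epochs=2, batch_size=4, phase="finetune"))
        np.testing.assert_array_equal(model.stem.weight.data, stem_before)
        assert not np.allclose(model.head_heat.out.weight.data, head_before)

    def test_lr_schedule(self):
        pre = TrainConfig(phase="pretrain")
        fin = TrainConfig(phase="finetune")
        assert pre.lr_at(0) == 5e-4 and pre.lr_at(60) == 2.5e-4
        assert fin.lr_at(0) == 1e-4 and fin.lr_at(50) == 5e-5 \
            and fin.lr_at(100) == 2.5e-5
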