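"""Field-of-view detection, canonical cropping and contrast enhancement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import convolve2d

from retvasc.errors import DegenerateBounds, NoFundusDetected
from retvasc.preprocess import (
    FrameTransform,
    FundusBounds,
    PreprocessConfig,
    _mirror_fill,
    crop_and_resize,
    detect_bounds,
    enhance_contrast,
    preprocess,
    resample_mask,
)
from retvasc.synthetic import generate_scene, random_scene_config

from conftest import disk_image


class TestDetectBounds:
    def test_recovers_planted_circle(self):
        img = disk_image((1024, 1024), (512, 512), 500)
        b = detect_bounds(img)
        assert np.hypot(b.center_x - 512, b.center_y - 512) < 2
        assert abs(b.radius - 500) / 500 < 0.01
        assert b.top is None and b.bottom is None

    def test_clipped_circle_reports_edge_lines(self):
        img = disk_image((768, 1024), (512, 384), 450)
        b = detect_bounds(img)
        assert b.top is not None and b.top <= 1
        assert b.bottom is not None and b.bottom >= 766
        assert b.left is None and b.right is None
        assert abs(b.radius - 450) / 450 < 0.01

    def test_all_zeros_raises(self):
        with pytest.raises(NoFundusDetected):
            detect_bounds(np.zeros((256, 256, 3)))

    def test_recovery_over_random_scenes(self):
        for i in range(6):
            scene = generate_scene(
                random_scene_config(400 + i, frame_size=512, edge_clip=i % 2 == 1)
            )
            b = detect_bounds(scene.image)
            tb = scene.bounds_truth
            assert np.hypot(b.center_x - tb.center_x, b.center_y - tb.center_y) < 2
            assert abs(b.radius - tb.radius) / tb.radius < 0.01
            for attr in ("top", "bottom", "left", "right"):
                assert (getattr(b, attr) is None) == (getattr(tb, attr) is None)


class TestFrameTransform:
    @given(
        scale=st.floats(0.05, 20.0),
        ox=st.floats(-2000, 2000),
        oy=st.floats(-2000, 2000),
        x=st.floats(-5000, 5000),
        y=st.floats(-5000, 5000),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity(self, scale, ox, oy, x, y):
        t = FrameTransform(scale=scale, offset_x=ox, offset_y=oy)
        p = np.array([[x, y]])
        assert np.allclose(t.inverse(t.forward(p)), p, atol=1e-9 * max(1, abs(x), abs(y)))

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            FrameTransform(scale=0.0, offset_x=0, offset_y=0)


class TestCropAndResize:
    def test_scale_is_target_over_diameter(self):
        img = disk_image((1024, 1024), (512, 512), 400)
        b = FundusBounds(512, 512, 400)
        _, t, _ = crop_and_resize(img, b, PreprocessConfig(target_size=1024))
        assert t.scale == pytest.approx(1024 / 800, rel=1e-9)

    def test_centered_circle_maps_to_frame_center(self):
        img = disk_image((2048, 2048), (1024, 1024), 1000)
        b = FundusBounds(1024, 1024, 1000)
        out, t, bt = crop_and_resize(img, b, PreprocessConfig(target_size=1024))
        assert out.shape == (1024, 1024, 3)
        assert (bt.center_x, bt.center_y) == pytest.approx((512, 512), abs=1e-6)
        assert bt.radius == pytest.approx(512, abs=1e-6)

    def test_degenerate_bounds(self):
        img = disk_image((256, 256), (128, 128), 50)
        # lines collapse the bounded region to a single point
        bad = FundusBounds(128, 128, 50, left=128.0, right=128.0,
                           top=128.0, bottom=128.0)
        with pytest.raises(DegenerateBounds):
            crop_and_resize(img, bad, PreprocessConfig(target_size=64))

    def test_mask_resampling_preserves_labels(self):
        mask = np.zeros((256, 256), np.uint8)
        mask[100:140, 80:120] = 3
        b = FundusBounds(128, 128, 100)
        _, t, _ = crop_and_resize(disk_image((256, 256), (128, 128), 100), b,
                                  PreprocessConfig(target_size=128))
        out = resample_mask(mask, t)
        assert set(np.unique(out)) <= {0, 3}
        assert out.shape == (128, 128)


class TestEnhanceContrast:
    CFG = PreprocessConfig(target_size=128, enhance_sigma_fraction=0.05)

    def test_constant_interior_maps_to_offset(self):
        img = np.full((128, 128, 3), 0.6)
        b = FundusBounds(64, 64, 50)
        out = enhance_contrast(img, b, self.CFG)
        inside = b.mask((128, 128))
        assert np.allclose(out[inside], self.CFG.enhance_offset, atol=1e-6)

    def test_exterior_blackout(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.2, 0.9, (128, 128, 3))
        b = FundusBounds(64, 64, 45)
        out = enhance_contrast(img, b, self.CFG)
        assert np.all(out[~b.mask((128, 128))] == 0)

    def test_bright_spot_center_surround(self):
        img = np.full((128, 128, 3), 0.3)
        img[62:67, 62:67] = 1.0
        b = FundusBounds(64, 64, 55)
        out = enhance_contrast(img, b, self.CFG)
        assert out[64, 64, 0] > self.CFG.enhance_offset
        # immediate surround (within ~sigma) dips below the offset
        assert out[64, 75, 0] < self.CFG.enhance_offset

    def test_matches_dense_convolution_oracle(self):
        """Direct convolution with an explicit Gaussian kernel reproduces the
        enhancement away from the FOV boundary."""
        rng = np.random.default_rng(1)
        img = rng.uniform(0.2, 0.8, (128, 128, 3))
        b = FundusBounds(64, 64, 52)
        cfg = self.CFG
        out = enhance_contrast(img, b, cfg)
        sigma = cfg.enhance_sigma_fraction * cfg.target_size
        half = int(np.ceil(4 * sigma))
        ax = np.arange(-half, half + 1)
        kern = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
        kern /= kern.sum()
        mirrored = _mirror_fill(img, b)
        blurred = convolve2d(mirrored[..., 0], kern, mode="same", boundary="symm")
        oracle = np.clip(
            cfg.enhance_gain * (mirrored[..., 0] - blurred) + cfg.enhance_offset, 0, 1
        )
        yy, xx = np.mgrid[0:128, 0:128]
        core = (xx - 64) ** 2 + (yy - 64) ** 2 <= (52 - 3 * sigma) ** 2
        assert np.allclose(out[..., 0][core], oracle[core], atol=2e-3)

    def test_mirror_padding_canvas_invariance(self):
        """Embedding the same FOV in a larger black canvas changes the
        enhancement only within ~sigma of the boundary."""
        rng = np.random.default_rng(2)
        n = 184  # leaves > 4 sigma of mirror band around the FOV circle
        small = rng.uniform(0.2, 0.9, (n, n, 3))
        b_small = FundusBounds(n / 2, n / 2, 60)
        small[~b_small.mask((n, n))] = 0
        pad = 40
        big = np.zeros((n + 2 * pad, n + 2 * pad, 3))
        big[pad : pad + n, pad : pad + n] = small
        b_big = FundusBounds(n / 2 + pad, n / 2 + pad, 60)
        cfg = self.CFG
        out_s = enhance_contrast(small, b_small, cfg)
        out_b = enhance_contrast(big, b_big, cfg)[pad : pad + n, pad : pad + n]
        sigma = cfg.enhance_sigma_fraction * cfg.target_size
        yy, xx = np.mgrid[0:n, 0:n]
        interior = (xx - n / 2) ** 2 + (yy - n / 2) ** 2 <= (60 - sigma) ** 2
        assert np.max(np.abs(out_s[interior] - out_b[interior])) <= 1 / 255


class TestPreprocessPipeline:
    def test_scene_roundtrip(self):
        scene = generate_scene(random_scene_config(11, frame_size=512))
        cfg = PreprocessConfig(target_size=512)
        result = preprocess(scene.image, cfg)
        assert result.cropped.shape == (512, 512, 3)
        assert result.enhanced.shape == (512, 512, 3)
        # canonical frame: FOV fills the square
        assert result.bounds_in_target.radius == pytest.approx(256, rel=0.02)
        # exterior of enhanced is blacked out
        outside = ~result.bounds_in_target.mask((512, 512))
        assert np.all(result.enhanced[outside] == 0)
        # six-channel stack order: cropped first, enhanced second
        stack = result.six_channel
        assert stack.shape == (512, 512, 6)
        assert np.array_equal(stack[..., :3], result.cropped)

    def test_idempotent_bounds_on_cropped(self):
        scene = generate_scene(random_scene_config(12, frame_size=512))
        result = preprocess(scene.image, PreprocessConfig(target_size=512))
        again = detect_bounds(result.cropped, PreprocessConfig(target_size=512))
        assert np.hypot(again.center_x - 256, again.center_y - 256) < 2

    def test_all_black_raises(self):
        with pytest.raises(NoFundusDetected):
            preprocess(np.zeros((512, 512, 3)))
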