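"""Preprocessing chain: frame transforms, thresholding, corpus splitting."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wellpred.preprocess import (AugmentSpec, augment, center_crop,
                                 interp_time, preprocess_corpus,
                                 preprocess_video, resize_bilinear,
                                 split_train_val, to_hsv, to_rgb,
                                 triangle_threshold, truncate_static,
                                 withhold_test)
from wellpred.video import VideoCorpus, VideoSequence
from wellpred.wellsim import SimConfig, generate_corpus


def _video(frames, colorspace="RGB", seq_id="v0"):
    return VideoSequence(frames=np.asarray(frames, float),
                         colorspace=colorspace, seq_id=seq_id)


def _random_video(rng, t=14, side=24, seq_id="v0"):
    return _video(rng.random((t, side, side, 3)), seq_id=seq_id)


def _corpus(n, rng, t=14, side=24):
    return VideoCorpus(sequences=[_random_video(rng, t, side, f"v{i:02d}")
                                  for i in range(n)])


class TestTruncate:
    def test_keeps_first_seven_of_fourteen(self, rng):
        out = truncate_static(_random_video(rng), keep=7)
        assert out.n_frames == 7

    def test_keep_equal_length_is_identity(self, rng):
        v = _random_video(rng, t=5)
        out = truncate_static(v, keep=5)
        assert np.array_equal(out.frames, v.frames)

    def test_too_short_raises(self, rng):
        with pytest.raises(ValueError):
            truncate_static(_random_video(rng, t=3), keep=7)


class TestHSV:
    def test_pure_colors_closed_form(self):
        frames = np.zeros((1, 2, 2, 3))
        frames[0, 0, 0] = [0, 1, 0]  # pure green
        frames[0, 0, 1] = [1, 0, 0]  # pure red
        out = to_hsv(_video(frames))
        np.testing.assert_allclose(out.frames[0, 0, 0], [1 / 3, 1, 1], atol=1e-12)
        np.testing.assert_allclose(out.frames[0, 0, 1], [0, 1, 1], atol=1e-12)

    def test_matches_scalar_conversion_oracle(self, rng):
        """Frame-level conversion equals the per-pixel colorsys loop."""
        v = _random_video(rng, t=2, side=8)
        out = to_hsv(v)
        for t in range(2):
            for i in range(8):
                for j in range(8):
                    exp = colorsys.rgb_to_hsv(*v.frames[t, i, j])
                    np.testing.assert_allclose(out.frames[t, i, j], exp,
                                               atol=1e-12)

    def test_round_trip(self, rng):
        v = _random_video(rng, t=3, side=6)
        back = to_rgb(to_hsv(v))
        np.testing.assert_allclose(back.frames, v.frames, atol=1e-6)

    def test_double_conversion_raises(self, rng):
        v = to_hsv(_random_video(rng, t=2, side=4))
        with pytest.raises(ValueError):
            to_hsv(v)


def _triangle_oracle(hist):
    """Exhaustive perpendicular-distance maximization over all bins."""
    hist = np.asarray(hist, float)
    nonzero = np.flatnonzero(hist)
    peak = int(np.argmax(hist))
    first, last = int(nonzero[0]), int(nonzero[-1])
    if first == last:
        return first
    tail = last if (last - peak) >= (peak - first) else first
    if tail == peak:
        return peak
    x1, y1, x2, y2 = float(peak), hist[peak], float(tail), hist[tail]
    norm = np.hypot(y2 - y1, x2 - x1)
    best, best_d = None, -1.0
    lo, hi = min(peak, tail), max(peak, tail)
    for b in range(lo, hi + 1):
        d = abs((y2 - y1) * b - (x2 - x1) * hist[b] + x2 * y1 - y2 * x1) / norm
        if d > best_d:
            best, best_d = b, d
    return best


class TestTriangleThreshold:
    def test_two_spikes_threshold_between(self):
        hist = np.zeros(256)
        hist[10], hist[200] = 1000, 10
        level = triangle_threshold(hist)
        assert 10 < level < 200

    def test_single_spike_returns_that_bin(self):
        hist = np.zeros(256)
        hist[77] = 5
        assert triangle_threshold(hist) == 77

    def test_matches_bruteforce_oracle_on_random_histograms(self):
        """100 random unimodal-with-tail histograms agree with exhaustive
        distance maximization."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            peak = rng.integers(5, 100)
            x = np.arange(256)
            hist = 1000 * np.exp(-0.5 * ((x - peak) / rng.uniform(2, 10)) ** 2)
            hist += rng.uniform(0, 5, 256) * (x > peak)
            hist = np.round(hist)
            assert triangle_threshold(hist) == _triangle_oracle(hist)

    def test_agrees_with_skimage_on_an_image(self):
        """Cross-check against skimage's triangle threshold on an 8-bit image."""
        from skimage.filters import threshold_triangle
        rng = np.random.default_rng(9)
        img = np.clip(rng.normal(30, 8, (64, 64)), 0, 255).astype(np.uint8)
        img[20:30, 20:30] = 220  # bright object on a dark unimodal background
        hist = np.bincount(img.ravel(), minlength=256)
        ours = triangle_threshold(hist)
        theirs = threshold_triangle(img)
        assert abs(ours - theirs) <= 2  # implementations differ by tie-breaks


class TestCenterCrop:
    @staticmethod
    def _disk_video(cy, cx, side=24, radius=4):
        rr, cc = np.mgrid[0:side, 0:side]
        disk = ((rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2).astype(float)
        frames = np.zeros((3, side, side, 3))
        frames[..., 1] = disk
        return _video(frames)

    def test_centered_disk_is_unchanged_window(self):
        v = self._disk_video(11.5, 11.5)
        out = center_crop(v, side=24)
        assert out.shape == v.shape
        np.testing.assert_allclose(out.frames, v.frames)

    def test_offset_disk_recentered(self):
        """Crop center lands within 1 px of the disk centroid."""
        v = self._disk_video(11.5 + 3, 11.5 + 2, side=32)
        out = center_crop(v, side=24)
        bright = out.frames[0, ..., 1]
        ys, xs = np.nonzero(bright > 0.5)
        cy, cx = ys.mean(), xs.mean()
        assert abs(cy - 11.5) <= 1.0 and abs(cx - 11.5) <= 1.0

    def test_all_black_falls_back_to_center(self, caplog):
        v = _video(np.zeros((2, 24, 24, 3)))
        with caplog.at_level("WARNING"):
            out = center_crop(v, side=16)
        assert out.shape == (2, 16, 16, 3)
        assert any("falling back" in r.message for r in caplog.records)


class TestInterpTime:
    def test_seven_to_twenty(self, rng):
        out = interp_time(_random_video(rng, t=7), n_out=20)
        assert out.n_frames == 20

    def test_identity_when_counts_match(self, rng):
        v = _random_video(rng, t=5)
        out = interp_time(v, n_out=5)
        np.testing.assert_allclose(out.frames, v.frames, atol=1e-12)

    def test_midpoint_is_average(self):
        frames = np.stack([np.zeros((4, 4, 3)), np.ones((4, 4, 3))])
        out = interp_time(_video(frames), n_out=3)
        np.testing.assert_allclose(out.frames[1], 0.5)

    def test_endpoints_exact(self, rng):
        v = _random_video(rng, t=7)
        out = interp_time(v, n_out=20)
        np.testing.assert_array_equal(out.frames[0], v.frames[0])
        np.testing.assert_array_equal(out.frames[-1], v.frames[-1])

    def test_single_frame_raises(self, rng):
        with pytest.raises(ValueError):
            interp_time(_random_video(rng, t=1), n_out=5)


class TestResize:
    def test_24_to_32(self, rng):
        out = resize_bilinear(_random_video(rng), side=32)
        assert out.shape == (14, 32, 32, 3)

    def test_constant_preserved(self):
        v = _video(np.full((2, 24, 24, 3), 0.37))
        out = resize_bilinear(v, side=32)
        np.testing.assert_allclose(out.frames, 0.37, atol=1e-12)

    def test_gradient_monotone_columns(self):
        frames = np.zeros((1, 2, 2, 3))
        frames[0, :, 1, :] = 1.0  # [[0,1],[0,1]]
        out = resize_bilinear(_video(frames), side=4)
        cols = out.frames[0, 0, :, 0]
        assert np.all(np.diff(cols) >= 0)
        assert cols[0] < cols[-1]


class TestSplits:
    def test_withhold_five_of_fortyeight(self, rng):
        corpus = _corpus(48, rng, t=3, side=6)
        out = withhold_test(corpus, n_test=5, rng=np.random.default_rng(1))
        labels = list(out.split_labels.values())
        assert labels.count("test") == 5
        assert labels.count("unassigned") == 43

    def test_withhold_zero(self, rng):
        corpus = _corpus(6, rng, t=2, side=4)
        out = withhold_test(corpus, n_test=0)
        assert "test" not in out.split_labels.values()

    def test_withhold_deterministic(self, rng):
        corpus = _corpus(20, rng, t=2, side=4)
        a = withhold_test(corpus, n_test=4, rng=np.random.default_rng(9))
        b = withhold_test(corpus, n_test=4, rng=np.random.default_rng(9))
        assert a.split_labels == b.split_labels

    def test_withhold_too_many_raises(self, rng):
        corpus = _corpus(5, rng, t=2, side=4)
        with pytest.raises(ValueError):
            withhold_test(corpus, n_test=5)

    def test_split_80_20_clip_mode(self, rng):
        corpus = _corpus(100, rng, t=2, side=4)
        out = split_train_val(corpus, train_frac=0.8, mode="clip",
                              rng=np.random.default_rng(0))
        labels = list(out.split_labels.values())
        assert labels.count("train") == 80
        assert labels.count("val") == 20

    def test_split_guards_minimum_val(self, rng):
        corpus = _corpus(2, rng, t=2, side=4)
        out = split_train_val(corpus, train_frac=0.99, mode="clip",
                              rng=np.random.default_rng(0))
        labels = list(out.split_labels.values())
        assert labels.count("val") >= 1

    def test_split_bad_fraction_raises(self, rng):
        with pytest.raises(ValueError):
            split_train_val(_corpus(4, rng, t=2, side=4), train_frac=1.5)

    def test_lineage_mode_no_source_straddles_split(self, rng):
        corpus = _corpus(10, rng, t=2, side=8)
        corpus = withhold_test(corpus, n_test=2, rng=np.random.default_rng(4))
        spec = AugmentSpec(target_corpus_size=40, rng_seed=0)
        corpus = augment(corpus, spec, rng=np.random.default_rng(4))
        out = split_train_val(corpus, mode="lineage",
                              rng=np.random.default_rng(4))
        train_roots = {s.root_source for s in out.subset("train")}
        val_roots = {s.root_source for s in out.subset("val")}
        assert not train_roots & val_roots


class TestAugment:
    def test_no_copies_when_target_met(self, rng):
        corpus = _corpus(5, rng, t=2, side=4)
        out = augment(corpus, AugmentSpec(target_corpus_size=5),
                      rng=np.random.default_rng(0))
        assert len(out) == 5

    def test_43_sources_to_392_total(self, rng):
        corpus = _corpus(48, rng, t=2, side=8)
        corpus = withhold_test(corpus, n_test=5, rng=np.random.default_rng(2))
        out = augment(corpus, AugmentSpec(target_corpus_size=392),
                      rng=np.random.default_rng(2))
        assert len(out) == 392
        # test sequences were never used as augmentation sources
        test_ids = {sid for sid, lab in out.split_labels.items() if lab == "test"}
        for s in out:
            if s.lineage.get("source"):
                assert s.lineage["source"] not in test_ids

    def test_hflip_is_involution(self, rng):
        from wellpred.preprocess import _apply_transform
        v = _random_video(rng, t=3, side=6)
        spec = AugmentSpec()
        once = _apply_transform(v.frames, "hflip", spec, rng)
        twice = _apply_transform(once, "hflip", spec, rng)
        np.testing.assert_array_equal(twice, v.frames)

    def test_unreachable_target_raises(self, rng):
        corpus = _corpus(2, rng, t=2, side=4)
        spec = AugmentSpec(transforms=("hflip",), max_depth=1,
                           target_corpus_size=100)
        with pytest.raises(ValueError, match="unreachable"):
            augment(corpus, spec, rng=np.random.default_rng(0))

    def test_geometric_transforms_commute_with_frame_stacking(self, rng):
        """Applying a geometric transform to the stack equals applying it
        frame by frame."""
        from wellpred.preprocess import _apply_transform
        v = _random_video(rng, t=4, side=6)
        spec = AugmentSpec()
        for name in ("hflip", "vflip", "rot90", "rot180", "rot270"):
            whole = _apply_transform(v.frames, name, spec, rng)
            per_frame = np.stack([
                _apply_transform(v.frames[t:t + 1], name, spec, rng)[0]
                for t in range(4)])
            np.testing.assert_array_equal(whole, per_frame)


class TestFullChain:
    def test_chain_shape_contract(self, rng):
        """A 14-frame 24x24 RGB video becomes a 20-frame 32x32 HSV video."""
        v = _random_video(rng, t=14, side=24)
        out = preprocess_video(v)
        assert out.shape == (20, 32, 32, 3)
        assert out.colorspace == "HSV"

    def test_corpus_chain_deterministic_manifest(self):
        cfg = SimConfig(rng_seed=31, n_frames=14)
        corpus = generate_corpus(cfg, n_videos=8)
        spec = AugmentSpec(target_corpus_size=20, rng_seed=5)
        a = preprocess_corpus(corpus, spec=spec, n_test=2,
                              rng=np.random.default_rng(5))
        b = preprocess_corpus(corpus, spec=spec, n_test=2,
                              rng=np.random.default_rng(5))
        assert a.manifest() == b.manifest()

    def test_no_test_descendants_in_train_or_val(self):
        cfg = SimConfig(rng_seed=13, n_frames=14)
        corpus = generate_corpus(cfg, n_videos=8)
        spec = AugmentSpec(target_corpus_size=24, rng_seed=1)
        for mode in ("clip", "lineage"):
            out = preprocess_corpus(corpus, spec=spec, n_test=2,
                                    split_mode=mode,
                                    rng=np.random.default_rng(1))
            test_roots = {s.root_source for s in out.subset("test")}
            for split in ("train", "val"):
                for s in out.subset(split):
                    assert s.root_source not in test_roots


@settings(deadline=None, max_examples=25, derandomize=True)
@given(t_in=st.integers(2, 10), n_out=st.integers(2, 30))
def test_interp_time_property_endpoints_and_length(t_in, n_out):
    rng = np.random.default_rng(t_in * 100 + n_out)
    v = VideoSequence(frames=rng.random((t_in, 4, 4, 3)))
    out = interp_time(v, n_out=n_out)
    assert out.n_frames == n_out
    np.testing.assert_array_equal(out.frames[0], v.frames[0])
    np.testing.assert_array_equal(out.frames[-1], v.frames[-1])
    assert out.frames.min() >= 0 and out.frames.max() <= 1
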