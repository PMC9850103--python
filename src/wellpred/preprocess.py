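"""Preprocessing chain turning raw microwell videos into a training corpus.

The chain mirrors a standard fluorescence-video preparation recipe:

1. drop the static post-saturation tail (keep the first 7 of 14 frames);
2. convert RGB to HSV, so species (hue), concentration (saturation) and
   presence (value) separate into channels;
3. recenter by cropping a square around the brightest pixels of the
   time-averaged frame after triangle thresholding;
4. interpolate in time (7 -> 20 frames) and resize with bilinear
   interpolation (24x24 -> 32x32);
5. withhold a test set, augment the rest (flips, rotations, blur, noise) to
   a target corpus size, and split train/validation 80/20.

All operations are pure: they return new :class:`VideoSequence` /
:class:`VideoCorpus` objects with updated lineage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color

from .video import (HSV, RGB, SPLIT_TEST, SPLIT_TRAIN, SPLIT_UNASSIGNED,
                    SPLIT_VAL, VideoCorpus, VideoSequence)

logger = logging.getLogger(__name__)

GEOMETRIC_TRANSFORMS = ("hflip", "vflip", "rot90", "rot180", "rot270")
DEFAULT_TRANSFORMS = GEOMETRIC_TRANSFORMS + ("gaussian_blur", "gaussian_noise")


@dataclass(frozen=True)
class AugmentSpec:
    """Which transforms may be composed, and how large the corpus must get."""

    transforms: tuple[str, ...] = DEFAULT_TRANSFORMS
    max_depth: int = 2
    target_corpus_size: int = 392
    blur_sigma: float = 0.5
    noise_sigma: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.transforms) - set(DEFAULT_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


# ----------------------------------------------------------- frame-level ops
def truncate_static(video: VideoSequence, keep: int = 7) -> VideoSequence:
    """Keep the first ``keep`` frames (dropping the static saturated tail)."""
    if video.n_frames < keep:
        raise ValueError(f"video has {video.n_frames} frames, cannot keep {keep}")
    return video.with_frames(video.frames[:keep], transform=f"truncate({keep})")


def to_hsv(video: VideoSequence) -> VideoSequence:
    """Hexcone RGB -> HSV conversion; all channels end up in [0, 1]."""
    if video.colorspace == HSV:
        raise ValueError("video is already HSV")
    frames = np.stack([color.rgb2hsv(f) for f in video.frames])
    return video.with_frames(frames, transform="to_hsv", colorspace=HSV)


def to_rgb(video: VideoSequence) -> VideoSequence:
    """Inverse of :func:`to_hsv`."""
    if video.colorspace == RGB:
        raise ValueError("video is already RGB")
    frames = np.stack([color.hsv2rgb(f) for f in video.frames])
    return video.with_frames(frames, transform="to_rgb", colorspace=RGB)


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle (Zack) threshold on a histogram of counts.

    Draws the line from the histogram peak to the farthest nonzero tail bin
    and returns the bin index maximizing the perpendicular distance between
    the histogram and that line.  If all mass sits in a single bin, that bin
    is returned.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size == 0:
        raise ValueError("histogram must be a non-empty 1-D array")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 0:
        raise ValueError("histogram is all zeros")
    peak = int(np.argmax(hist))
    first, last = int(nonzero[0]), int(nonzero[-1])
    if first == last:
        return first
    # tail = nonzero end farther from the peak
    tail = last if (last - peak) >= (peak - first) else first
    if tail == peak:
        return peak
    lo, hi = (peak, tail) if peak < tail else (tail, peak)
    bins = np.arange(lo, hi + 1, dtype=np.float64)
    # perpendicular distance from (b, h[b]) to the peak-tail line
    x1, y1 = float(peak), hist[peak]
    x2, y2 = float(tail), hist[tail]
    num = np.abs((y2 - y1) * bins - (x2 - x1) * hist[lo:hi + 1] + x2 * y1 - y2 * x1)
    return int(lo + np.argmax(num))  # denominator is constant along the line


def _brightness(video: VideoSequence) -> np.ndarray:
    """Per-frame brightness channel: V if HSV, max over RGB otherwise."""
    if video.colorspace == HSV:
        return video.frames[..., 2]
    return video.frames.max(axis=-1)


def center_crop(video: VideoSequence, side: int = 24) -> VideoSequence:
    """Crop a ``side`` x ``side`` window centered on the bright region.

    Brightness is averaged over time, triangle-thresholded on a 256-bin
    histogram, and the centroid of suprathreshold pixels becomes the crop
    center (rounded).  The window is zero-padded where it exits the frame.
    With no suprathreshold pixel the geometric image center is used and a
    warning logged.
    """
    mean_b = _brightness(video).mean(axis=0)
    h, w = mean_b.shape
    hist, edges = np.histogram(mean_b, bins=256, range=(0.0, 1.0))
    level = triangle_threshold(hist)
    thresh = edges[level + 1]  # pixels strictly brighter than the level bin
    ys, xs = np.nonzero(mean_b > thresh)
    if ys.size == 0:
        logger.warning("center_crop: no suprathreshold pixel in %s; "
                       "falling back to geometric center", video.seq_id)
        cy, cx = (h - 1) / 2, (w - 1) / 2
    else:
        weights = mean_b[ys, xs]
        cy = float(np.average(ys, weights=weights))
        cx = float(np.average(xs, weights=weights))
    top = int(round(cy)) - side // 2
    left = int(round(cx)) - side // 2
    out = np.zeros((video.n_frames, side, side, 3))
    y0, y1 = max(top, 0), min(top + side, h)
    x0, x1 = max(left, 0), min(left + side, w)
    out[:, y0 - top:y1 - top, x0 - left:x1 - left, :] = video.frames[:, y0:y1, x0:x1, :]
    return video.with_frames(out, transform=f"center_crop({side})")


def interp_time(video: VideoSequence, n_out: int = 20) -> VideoSequence:
    """Per-pixel linear interpolation to ``n_out`` uniformly spaced frames.

    Output positions span [0, T-1]; the first and last output frames equal
    the first and last input frames exactly.
    """
    t_in = video.n_frames
    if t_in < 2:
        raise ValueError("temporal interpolation needs at least 2 frames")
    pos = np.linspace(0.0, t_in - 1, n_out)
    lo = np.clip(np.floor(pos).astype(int), 0, t_in - 2)
    frac = (pos - lo)[:, None, None, None]
    frames = (1 - frac) * video.frames[lo] + frac * video.frames[lo + 1]
    # exact endpoints, immune to floating-point roundoff in frac
    frames[0] = video.frames[0]
    frames[-1] = video.frames[-1]
    return video.with_frames(frames, transform=f"interp_time({n_out})")


def resize_bilinear(video: VideoSequence, side: int = 32) -> VideoSequence:
    """Bilinear resize of every frame to ``side`` x ``side``.

    Uses the half-pixel-center convention: output pixel i samples input
    coordinate (i + 0.5) * scale - 0.5, clipped at the borders.  Stated
    explicitly because resize dialects differ by a half-pixel shift.
    """
    t, h, w, _ = video.shape
    if h != w:
        raise ValueError("frames must be square")
    coords = np.clip((np.arange(side) + 0.5) * (h / side) - 0.5, 0, h - 1)
    rows, cols = np.meshgrid(coords, coords, indexing="ij")
    out = np.empty((t, side, side, 3))
    for ti in range(t):
        for ch in range(3):
            out[ti, ..., ch] = ndimage.map_coordinates(
                video.frames[ti, ..., ch], [rows, cols], order=1, mode="nearest")
    return video.with_frames(out, transform=f"resize({side})")


# ----------------------------------------------------------- corpus-level ops
def withhold_test(corpus: VideoCorpus, n_test: int = 5,
                  rng: np.random.Generator | None = None) -> VideoCorpus:
    """Uniformly sample ``n_test`` sequences and label them as the test set.

    Test sequences and any future descendants are excluded from augmentation
    and training.  Must run before augmentation.
    """
    if any(s.lineage.get("source") for s in corpus):
        raise ValueError("withhold_test must run before augmentation")
    if n_test >= len(corpus):
        raise ValueError(f"n_test={n_test} >= corpus size {len(corpus)}")
    rng = np.random.default_rng(0) if rng is None else rng
    out = corpus.copy_shallow()
    if n_test > 0:
        ids = sorted(out.split_labels)
        chosen = rng.choice(len(ids), size=n_test, replace=False)
        for i in chosen:
            out.split_labels[ids[i]] = SPLIT_TEST
    return out


def _apply_transform(frames: np.ndarray, name: str, spec: AugmentSpec,
                     rng: np.random.Generator) -> np.ndarray:
    if name == "hflip":
        return frames[:, :, ::-1, :]
    if name == "vflip":
        return frames[:, ::-1, :, :]
    if name.startswith("rot"):
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[name]
        return np.rot90(frames, k=k, axes=(1, 2))
    if name == "gaussian_blur":
        out = np.empty_like(frames)
        for t in range(frames.shape[0]):
            for ch in range(3):
                out[t, ..., ch] = ndimage.gaussian_filter(
                    frames[t, ..., ch], spec.blur_sigma, mode="nearest")
        return out
    if name == "gaussian_noise":
        return np.clip(frames + rng.normal(0, spec.noise_sigma, frames.shape), 0, 1)
    raise ValueError(f"unknown transform {name!r}")


def _compositions(transforms: tuple[str, ...], max_depth: int):
    """All ordered compositions of distinct transforms up to ``max_depth``."""
    for depth in range(1, max_depth + 1):
        yield from itertools.permutations(transforms, depth)


def augment(corpus: VideoCorpus, spec: AugmentSpec,
            rng: np.random.Generator | None = None) -> VideoCorpus:
    """Grow the corpus to ``spec.target_corpus_size`` with augmented copies.

    Only non-test sequences are eligible sources.  (source, composition)
    pairs are sampled without replacement per source — no source receives
    the same composition twice — cycling round-robin over sources so copies
    spread evenly.  Geometric transforms are applied identically to every
    frame; all transforms are recorded in the copy's lineage in order.
    """
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    out = corpus.copy_shallow()
    sources = [s for s in corpus
               if out.split_labels[s.seq_id] != SPLIT_TEST
               and not s.lineage.get("source")]
    n_needed = spec.target_corpus_size - len(corpus)
    if n_needed < 0:
        raise ValueError("target_corpus_size smaller than current corpus")
    if n_needed == 0:
        return out
    if not sources:
        raise ValueError("no eligible (non-test) source sequences")
    all_comps = list(_compositions(spec.transforms, spec.max_depth))
    if n_needed > len(sources) * len(all_comps):
        raise ValueError(
            f"target {spec.target_corpus_size} unreachable: only "
            f"{len(sources) * len(all_comps)} distinct (source, composition) pairs")
    # per-source shuffled composition decks; deal round-robin
    decks = {s.seq_id: [all_comps[i] for i in rng.permutation(len(all_comps))]
             for s in sources}
    made = 0
    counter = 0
    while made < n_needed:
        for src in sources:
            if made >= n_needed:
                break
            deck = decks[src.seq_id]
            if not deck:
                continue
            comp = deck.pop()
            frames = src.frames
            for name in comp:
                frames = _apply_transform(frames, name, spec, rng)
            copy = src.with_frames(frames, seq_id=f"{src.seq_id}_aug{counter:04d}")
            copy.lineage["transforms"] = list(src.lineage["transforms"]) + list(comp)
            out.sequences.append(copy)
            out.split_labels[copy.seq_id] = SPLIT_UNASSIGNED
            made += 1
            counter += 1
    return out


def split_train_val(corpus: VideoCorpus, train_frac: float = 0.8,
                    mode: str = "lineage",
                    rng: np.random.Generator | None = None) -> VideoCorpus:
    """Label non-test sequences train/val in ``train_frac`` proportion.

    ``mode="clip"`` splits at random over individual sequences, which lets
    augmented copies of one source land on both sides.  ``mode="lineage"``
    (default) assigns whole lineages — a source and all its augmented
    copies — to one side, preventing leakage of near-duplicate clips into
    validation.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if mode not in ("clip", "lineage"):
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    out = corpus.copy_shallow()
    eligible = [s for s in corpus if out.split_labels[s.seq_id] != SPLIT_TEST]
    if len(eligible) < 2:
        raise ValueError("need at least 2 eligible sequences to split")
    n_train = int(round(train_frac * len(eligible)))
    n_train = min(n_train, len(eligible) - 1)  # >= 1 val sequence always
    n_train = max(n_train, 1)
    if mode == "clip":
        order = rng.permutation(len(eligible))
        for rank, i in enumerate(order):
            out.split_labels[eligible[i].seq_id] = (
                SPLIT_TRAIN if rank < n_train else SPLIT_VAL)
    else:
        roots: dict[str, list[str]] = {}
        for s in eligible:
            roots.setdefault(s.root_source, []).append(s.seq_id)
        root_ids = sorted(roots)
        order = rng.permutation(len(root_ids))
        assigned = 0
        train_roots = set()
        for i in order:
            if assigned >= n_train:
                break
            train_roots.add(root_ids[i])
            assigned += len(roots[root_ids[i]])
        # guard: leave at least one whole lineage in val
        if len(train_roots) == len(root_ids):
            train_roots.discard(root_ids[order[-1]])
        for root, members in roots.items():
            label = SPLIT_TRAIN if root in train_roots else SPLIT_VAL
            for sid in members:
                out.split_labels[sid] = label
    return out


# ------------------------------------------------------------------- chains
def preprocess_video(video: VideoSequence, keep: int = 7, crop_side: int = 24,
                     n_out_frames: int = 20, out_side: int = 32) -> VideoSequence:
    """The full single-video chain: truncate -> HSV -> crop -> interp -> resize."""
    v = truncate_static(video, keep=keep)
    v = to_hsv(v)
    v = center_crop(v, side=crop_side)
    v = interp_time(v, n_out=n_out_frames)
    return resize_bilinear(v, side=out_side)


def preprocess_corpus(corpus: VideoCorpus, spec: AugmentSpec | None = None,
                      n_test: int = 5, keep: int = 7, crop_side: int = 24,
                      n_out_frames: int = 20, out_side: int = 32,
                      train_frac: float = 0.8, split_mode: str = "lineage",
                      rng: np.random.Generator | None = None) -> VideoCorpus:
    """Full corpus pipeline: per-video chain, test withholding, augmentation
    to the target size, and train/val split."""
    spec = AugmentSpec() if spec is None else spec
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    processed = VideoCorpus(sequences=[
        preprocess_video(s, keep=keep, crop_side=crop_side,
                         n_out_frames=n_out_frames, out_side=out_side)
        for s in corpus])
    processed = withhold_test(processed, n_test=n_test, rng=rng)
    processed = augment(processed, spec, rng=rng)
    return split_train_val(processed, train_frac=train_frac, mode=split_mode,
                           rng=rng)
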