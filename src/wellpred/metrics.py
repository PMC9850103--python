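"""Prediction-quality metrics with microbiological meaning.

Beyond plain image error (per-frame MSE and a perceptual distance), the
module extracts the quantities a microbiologist would read off a
fluorescence video: per-strain population curves (pixel counts of green and
red fluorescence per frame) and colony statistics (connected components of
each strain's classified mask, with per-colony sizes and centroids).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as skcolor
from skimage import measure
from skimage.metrics import structural_similarity

from .video import HSV, RGB, VideoCorpus, VideoSequence

logger = logging.getLogger(__name__)


@dataclass
class FrameMetricSeries:
    """Per-frame metric values plus their arithmetic mean."""

    values: np.ndarray
    metric: str
    pixel_scale: str = "unit"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError(f"{self.metric} values must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)),
                             self.metric: self.values})


@dataclass(frozen=True)
class HueThresholds:
    """Pixel-classification bands on the HSV hexcone (hue in degrees).

    Green covers the fluorescent-protein band around 120 deg; red wraps
    through 0 deg.  ``v_min`` and ``s_min`` reject dim background pixels.
    """

    green_band: tuple[float, float] = (90.0, 150.0)
    red_band: tuple[float, float] = (330.0, 30.0)  # wraps through 0
    v_min: float = 0.1
    s_min: float = 0.1

    def __post_init__(self) -> None:
        # reject overlapping bands (red wraps, so unwrap before comparing)
        g0, g1 = self.green_band
        r0, r1 = self.red_band
        red_arcs = [(r0, 360.0), (0.0, r1)] if r0 > r1 else [(r0, r1)]
        for a0, a1 in red_arcs:
            if max(a0, g0) < min(a1, g1):
                raise ValueError("green and red hue bands overlap")


def frame_mse(predicted: VideoSequence, groundtruth: VideoSequence,
              scale: str = "255") -> FrameMetricSeries:
    """Per-frame mean squared error over pixels and channels.

    ``scale="255"`` reports errors with pixel values on 0-255 (the common
    convention for video-prediction MSE magnitudes); ``scale="unit"`` keeps
    the native [0, 1] range.
    """
    if predicted.shape != groundtruth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {groundtruth.shape}")
    if scale not in ("unit", "255"):
        raise ValueError("scale must be 'unit' or '255'")
    factor = 255.0 if scale == "255" else 1.0
    diff = (predicted.frames - groundtruth.frames) * factor
    values = np.mean(diff ** 2, axis=(1, 2, 3))
    return FrameMetricSeries(values=values, metric="mse", pixel_scale=scale)


def perceptual_score(predicted: VideoSequence, groundtruth: VideoSequence,
                     backend: str = "builtin_ssim_distance") -> FrameMetricSeries:
    """Perceptual dissimilarity per frame; 0 for identical frames.

    The default backend is a self-contained structural-dissimilarity
    distance, 1 - SSIM averaged over channels.  ``backend="lpips_plugin"``
    defers to a locally installed LPIPS implementation with pretrained
    weights and raises if none is importable — there is no silent fallback,
    since the two scores are not comparable.
    """
    if predicted.shape != groundtruth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {groundtruth.shape}")
    if backend == "builtin_ssim_distance":
        values = []
        for fp, fg in zip(predicted.frames, groundtruth.frames):
            ssim = structural_similarity(fp, fg, channel_axis=-1, data_range=1.0)
            values.append(max(0.0, 1.0 - ssim))
        return FrameMetricSeries(values=np.array(values),
                                 metric="ssim_distance", pixel_scale="unit")
    if backend == "lpips_plugin":
        try:
            import lpips  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "LPIPS backend requested but the 'lpips' package (and its "
                "pretrained weights) is not available; install it or use the "
                "builtin_ssim_distance backend") from exc
        import torch  # type: ignore
        net = lpips.LPIPS(net="alex")
        values = []
        for fp, fg in zip(predicted.frames, groundtruth.frames):
            ta = torch.from_numpy((fp * 2 - 1).transpose(2, 0, 1)[None]).float()
            tb = torch.from_numpy((fg * 2 - 1).transpose(2, 0, 1)[None]).float()
            values.append(float(net(ta, tb).item()))
        return FrameMetricSeries(values=np.array(values), metric="lpips",
                                 pixel_scale="unit")
    raise ValueError(f"unknown backend {backend!r}")


# --------------------------------------------------------- classification
def _as_hsv_frames(video: VideoSequence) -> np.ndarray:
    if video.colorspace == HSV:
        return video.frames
    return np.stack([skcolor.rgb2hsv(f) for f in video.frames])


def _strain_masks(hsv_frame: np.ndarray, thresholds: HueThresholds
                  ) -> tuple[np.ndarray, np.ndarray]:
    hue = hsv_frame[..., 0] * 360.0
    sat = hsv_frame[..., 1]
    val = hsv_frame[..., 2]
    bright = (val >= thresholds.v_min) & (sat >= thresholds.s_min)
    g0, g1 = thresholds.green_band
    green = bright & (hue >= g0) & (hue <= g1)
    r0, r1 = thresholds.red_band
    if r0 > r1:  # wrapped band
        red = bright & ((hue >= r0) | (hue <= r1))
    else:
        red = bright & (hue >= r0) & (hue <= r1)
    return green, red


@dataclass
class PopulationCurve:
    """Per-frame green and red classified pixel counts."""

    green_pixels: np.ndarray
    red_pixels: np.ndarray
    thresholds: HueThresholds = field(default_factory=HueThresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.green_pixels)),
                             "green_pixels": self.green_pixels,
                             "red_pixels": self.red_pixels})


def population_curve(video: VideoSequence,
                     thresholds: HueThresholds | None = None) -> PopulationCurve:
    """Strain abundance proxy: count green and red pixels per frame."""
    thresholds = thresholds or HueThresholds()
    hsv = _as_hsv_frames(video)
    greens, reds = [], []
    for frame in hsv:
        g, r = _strain_masks(frame, thresholds)
        greens.append(int(g.sum()))
        reds.append(int(r.sum()))
    return PopulationCurve(green_pixels=np.array(greens, dtype=np.int64),
                           red_pixels=np.array(reds, dtype=np.int64),
                           thresholds=thresholds)


@dataclass(frozen=True)
class ColonyRecord:
    """One connected component of one strain in one frame."""

    frame: int
    strain: str  # "G" or "R"
    colony_id: int
    size: int
    centroid: tuple[float, float]  # (row, col)


def colony_table(video: VideoSequence, connectivity: int = 8, min_size: int = 1,
                 thresholds: HueThresholds | None = None) -> list[ColonyRecord]:
    """Colonies per frame per strain via connected-component labeling.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent);
    components smaller than ``min_size`` pixels are dropped.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    thresholds = thresholds or HueThresholds()
    conn = 1 if connectivity == 4 else 2
    hsv = _as_hsv_frames(video)
    records: list[ColonyRecord] = []
    for t, frame in enumerate(hsv):
        green, red = _strain_masks(frame, thresholds)
        for strain, mask in (("G", green), ("R", red)):
            labels = measure.label(mask, connectivity=conn)
            for region in measure.regionprops(labels):
                if region.area >= min_size:
                    records.append(ColonyRecord(
                        frame=t, strain=strain, colony_id=int(region.label),
                        size=int(region.area),
                        centroid=(float(region.centroid[0]),
                                  float(region.centroid[1]))))
    return records


def colony_records_to_frame(records: list[ColonyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"frame": r.frame, "strain": r.strain, "colony_id": r.colony_id,
          "size": r.size, "centroid_row": r.centroid[0],
          "centroid_col": r.centroid[1]} for r in records],
        columns=["frame", "strain", "colony_id", "size",
                 "centroid_row", "centroid_col"])


# ---------------------------------------------------------------- reporting
def compare_report(groundtruth: VideoCorpus, predicted: VideoCorpus,
                   out_dir: str | Path, mse_scale: str = "255",
                   colony_frames: tuple[int, ...] = (11, 15, 19),
                   thresholds: HueThresholds | None = None,
                   input_len: int = 10) -> dict:
    """Side-by-side evaluation of predicted against groundtruth wells.

    For each matched sequence id, writes a frame montage PNG, per-frame
    MSE/perceptual curves, overlaid population curves, and colony count and
    size comparisons at ``colony_frames``; returns (and writes) a JSON
    summary of the scalar metrics.  Predicted sequences cover frames
    ``input_len ..`` of the groundtruth, as produced by the predictor.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt_ids = set(groundtruth.split_labels)
    pr_ids = set(predicted.split_labels)
    if gt_ids != pr_ids:
        raise ValueError(f"unmatched wells: groundtruth-only "
                         f"{sorted(gt_ids - pr_ids)}, predicted-only "
                         f"{sorted(pr_ids - gt_ids)}")
    thresholds = thresholds or HueThresholds()
    summary: dict = {"wells": {}, "mse_scale": mse_scale}
    all_mse, all_perc = [], []
    for sid in sorted(gt_ids):
        gt_seq = groundtruth.get(sid)
        pr_seq = predicted.get(sid)
        gt_tail = gt_seq.with_frames(
            gt_seq.frames[input_len:input_len + pr_seq.n_frames])
        mse = frame_mse(pr_seq, gt_tail, scale=mse_scale)
        perc = perceptual_score(pr_seq, gt_tail)
        pop_gt = population_curve(gt_seq, thresholds)
        pop_pr = population_curve(pr_seq, thresholds)
        col_gt = colony_records_to_frame(colony_table(gt_seq, thresholds=thresholds))
        col_pr = colony_records_to_frame(colony_table(pr_seq, thresholds=thresholds))

        _write_montage(plt, gt_tail, pr_seq, out / f"{sid}_montage.png")
        _write_curves(plt, mse, perc, pop_gt, pop_pr, input_len,
                      out / f"{sid}_curves.png")
        _write_colony_bars(plt, col_gt, col_pr, colony_frames, input_len,
                           out / f"{sid}_colonies.png")
        pop_gt.to_frame().to_csv(out / f"{sid}_population_gt.csv", index=False)
        pop_pr.to_frame().to_csv(out / f"{sid}_population_pred.csv", index=False)
        col_gt.to_csv(out / f"{sid}_colonies_gt.csv", index=False)
        col_pr.to_csv(out / f"{sid}_colonies_pred.csv", index=False)

        summary["wells"][sid] = {
            "mse_per_frame": mse.values.tolist(),
            "mse_mean": mse.mean,
            "perceptual_per_frame": perc.values.tolist(),
            "perceptual_mean": perc.mean,
        }
        all_mse.append(mse.mean)
        all_perc.append(perc.mean)
    summary["mean_mse"] = float(np.mean(all_mse)) if all_mse else 0.0
    summary["mean_perceptual"] = float(np.mean(all_perc)) if all_perc else 0.0
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _to_rgb_display(seq: VideoSequence) -> np.ndarray:
    if seq.colorspace == RGB:
        return seq.frames
    return np.stack([skcolor.hsv2rgb(f) for f in seq.frames])


def _write_montage(plt, gt_seq: VideoSequence, pr_seq: VideoSequence,
                   path: Path) -> None:
    gt_rgb, pr_rgb = _to_rgb_display(gt_seq), _to_rgb_display(pr_seq)
    n = gt_rgb.shape[0]
    fig, axes = plt.subplots(2, max(n, 1), figsize=(1.2 * n, 2.8))
    axes = np.atleast_2d(axes)
    for t in range(n):
        axes[0, t].imshow(np.clip(gt_rgb[t], 0, 1))
        axes[1, t].imshow(np.clip(pr_rgb[t], 0, 1))
        for row in range(2):
            axes[row, t].set_xticks([])
            axes[row, t].set_yticks([])
    axes[0, 0].set_ylabel("truth", fontsize=8)
    axes[1, 0].set_ylabel("predicted", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)


def _write_curves(plt, mse: FrameMetricSeries, perc: FrameMetricSeries,
                  pop_gt: PopulationCurve, pop_pr: PopulationCurve,
                  input_len: int, path: Path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    axes[0].plot(mse.values, "o-")
    axes[0].set_title(f"MSE ({mse.pixel_scale})")
    axes[1].plot(perc.values, "o-")
    axes[1].set_title(perc.metric)
    frames_gt = np.arange(len(pop_gt.green_pixels))
    frames_pr = input_len + np.arange(len(pop_pr.green_pixels))
    axes[2].plot(frames_gt, pop_gt.green_pixels, "g-", label="green truth")
    axes[2].plot(frames_gt, pop_gt.red_pixels, "r-", label="red truth")
    axes[2].plot(frames_pr, pop_pr.green_pixels, "g--", label="green pred")
    axes[2].plot(frames_pr, pop_pr.red_pixels, "r--", label="red pred")
    axes[2].set_title("population curves")
    axes[2].legend(fontsize=6)
    for ax in axes:
        ax.set_xlabel("frame")
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)


def _write_colony_bars(plt, col_gt: pd.DataFrame, col_pr: pd.DataFrame,
                       colony_frames: tuple[int, ...], input_len: int,
                       path: Path) -> None:
    fig, axes = plt.subplots(1, len(colony_frames),
                             figsize=(3 * len(colony_frames), 3), squeeze=False)
    for ax, frame in zip(axes[0], colony_frames):
        bars, labels = [], []
        for strain, color_ in (("G", "green"), ("R", "red")):
            n_gt = len(col_gt[(col_gt.frame == frame) & (col_gt.strain == strain)])
            n_pr = len(col_pr[(col_pr.frame == frame - input_len)
                              & (col_pr.strain == strain)])
            bars.extend([n_gt, n_pr])
            labels.extend([f"{strain} truth", f"{strain} pred"])
        ax.bar(range(len(bars)), bars,
               color=["green", "lightgreen", "red", "salmon"])
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, fontsize=6, rotation=45)
        ax.set_title(f"colonies, frame {frame}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)
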