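"""Core containers for fluorescence time-lapse videos and corpora.

A :class:`VideoSequence` is an ordered stack of frames with a colorspace tag
and provenance (lineage).  A :class:`VideoCorpus` is a set of sequences with
split labels (train / val / test / unassigned) and a lineage graph linking
augmented copies back to their source videos.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

RGB = "RGB"
HSV = "HSV"

SPLIT_TRAIN = "train"
SPLIT_VAL = "val"
SPLIT_TEST = "test"
SPLIT_UNASSIGNED = "unassigned"


@dataclass
class VideoSequence:
    """An ordered T x H x W x 3 frame stack with pixel values in [0, 1].

    Parameters
    ----------
    frames
        Float array of shape (T, H, W, 3), values in [0, 1].
    colorspace
        Either ``"RGB"`` or ``"HSV"``.
    frame_interval_min
        Acquisition cadence in minutes (30 for the modeled corpus).
    seq_id
        Unique identifier within a corpus.
    lineage
        Provenance: ``source`` (root sequence id, or None for originals),
        ``transforms`` (ordered list of transformation descriptions) and
        free-form metadata such as the seeding ``regime``.
    """

    frames: np.ndarray
    colorspace: str = RGB
    frame_interval_min: float = 30.0
    seq_id: str = "seq"
    lineage: dict = field(default_factory=dict)
    # per-frame ground-truth occupancy counts {"G": [...], "R": [...]} when the
    # sequence comes from the simulator; None for real or derived videos
    occupancy: dict | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {self.frames.shape}")
        # T = 0 is legal only as the degenerate output of a zero-horizon
        # prediction; all real videos have at least one frame
        if self.colorspace not in (RGB, HSV):
            raise ValueError(f"unknown colorspace {self.colorspace!r}")
        lo, hi = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"pixel values must lie in [0, 1]; found [{lo}, {hi}]")
        self.lineage.setdefault("source", None)
        self.lineage.setdefault("transforms", [])

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    def with_frames(self, frames: np.ndarray, transform: str | None = None,
                    colorspace: str | None = None, seq_id: str | None = None) -> "VideoSequence":
        """Derive a new sequence, appending ``transform`` to the lineage."""
        source = self.lineage.get("source")
        if seq_id is not None and seq_id != self.seq_id:
            # a renamed derivative is an augmented copy; track its origin
            source = source or self.seq_id
        lineage = {
            "source": source,
            "transforms": list(self.lineage["transforms"]) + ([transform] if transform else []),
        }
        for k, v in self.lineage.items():
            if k not in ("source", "transforms"):
                lineage[k] = v
        return VideoSequence(
            frames=np.clip(frames, 0.0, 1.0),
            colorspace=colorspace or self.colorspace,
            frame_interval_min=self.frame_interval_min,
            seq_id=seq_id or self.seq_id,
            lineage=lineage,
            occupancy=self.occupancy,
        )

    @property
    def root_source(self) -> str:
        """Id of the original (pre-augmentation) sequence this one descends from."""
        return self.lineage.get("source") or self.seq_id

    # ------------------------------------------------------------------ I/O
    def write_png_dir(self, out_dir: str | Path) -> Path:
        """Write frames as zero-padded 8-bit PNGs (``frame_000.png`` ...)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t in range(self.n_frames):
            frame8 = np.round(self.frames[t] * 255.0).astype(np.uint8)
            iio.imwrite(out / f"frame_{t:03d}.png", frame8)
        return out

    def write_tiff(self, path: str | Path) -> Path:
        """Write frames as a multi-page 8-bit TIFF stack."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        stack = np.round(self.frames * 255.0).astype(np.uint8)
        tifffile.imwrite(path, stack, photometric="rgb")
        return path

    @classmethod
    def read_png_dir(cls, in_dir: str | Path, seq_id: str | None = None,
                     colorspace: str = RGB) -> "VideoSequence":
        in_dir = Path(in_dir)
        paths = sorted(in_dir.glob("frame_*.png"))
        if not paths:
            raise FileNotFoundError(f"no frame_*.png files in {in_dir}")
        frames = np.stack([iio.imread(p) for p in paths]).astype(np.float64) / 255.0
        if frames.ndim == 3:  # grayscale PNGs
            frames = np.repeat(frames[..., None], 3, axis=-1)
        return cls(frames=frames, colorspace=colorspace, seq_id=seq_id or in_dir.name)

    @classmethod
    def read_tiff(cls, path: str | Path, seq_id: str | None = None,
                  colorspace: str = RGB) -> "VideoSequence":
        path = Path(path)
        stack = tifffile.imread(path).astype(np.float64) / 255.0
        return cls(frames=stack, colorspace=colorspace, seq_id=seq_id or path.stem)


@dataclass
class VideoCorpus:
    """A set of sequences with split labels and a lineage graph."""

    sequences: list[VideoSequence] = field(default_factory=list)
    split_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.seq_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in corpus")
        for sid in ids:
            self.split_labels.setdefault(sid, SPLIT_UNASSIGNED)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def get(self, seq_id: str) -> VideoSequence:
        for s in self.sequences:
            if s.seq_id == seq_id:
                return s
        raise KeyError(seq_id)

    def subset(self, split: str) -> list[VideoSequence]:
        return [s for s in self.sequences if self.split_labels[s.seq_id] == split]

    def ids(self, split: str | None = None) -> list[str]:
        if split is None:
            return [s.seq_id for s in self.sequences]
        return [s.seq_id for s in self.subset(split)]

    def copy_shallow(self) -> "VideoCorpus":
        return VideoCorpus(sequences=list(self.sequences),
                           split_labels=dict(self.split_labels))

    # -------------------------------------------------------------- manifest
    def manifest(self) -> dict:
        """JSON-serializable description of every sequence's provenance."""
        return {
            "n_sequences": len(self),
            "sequences": [
                {
                    "id": s.seq_id,
                    "n_frames": s.n_frames,
                    "height": int(s.frames.shape[1]),
                    "width": int(s.frames.shape[2]),
                    "colorspace": s.colorspace,
                    "split": self.split_labels[s.seq_id],
                    "source": s.lineage.get("source"),
                    "regime": s.lineage.get("regime"),
                    "transforms": list(s.lineage.get("transforms", [])),
                }
                for s in self.sequences
            ],
        }

    def write_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.manifest(), indent=2, sort_keys=True))
        return path

    def write_occupancy_csv(self, path: str | Path) -> Path:
        """Ground-truth per-frame strain pixel counts as tidy CSV."""
        rows = []
        for s in self.sequences:
            if s.occupancy is None:
                continue
            for strain in ("G", "R"):
                for frame, count in enumerate(s.occupancy[strain]):
                    rows.append({"sequence": s.seq_id, "frame": frame,
                                 "strain": strain, "pixel_count": int(count)})
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows, columns=["sequence", "frame", "strain", "pixel_count"]).to_csv(
            path, index=False)
        return path
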