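"""Stacked convolutional recurrent frame predictor, statsmodels-style.

:class:`FramePredictor` is the model object: it is built from training and
validation corpora plus a :class:`PredictorConfig`, and ``fit()`` returns a
:class:`FramePredictorResults` carrying the learned parameters, the training
history and prediction methods.

The network ingests ``input_len`` observed frames (teacher forcing) and then
feeds its own outputs back autoregressively for ``horizon`` steps; it is
trained by Adam on the mean-squared error between predicted and observed
frames over the prediction window.  Frames are space-to-depth folded by
``patch_size`` before entering the recurrence, the convention of
video-prediction recurrent networks: a 32x32x3 frame with patch 4 becomes an
8x8 map with 48 channels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .nn.autograd import Adam, Tensor
from .nn.cells import ConvGatedCell, STLSTMCell
from .video import VideoCorpus, VideoSequence
from .nn.autograd import conv2d

CELL_TYPES = ("dual_memory", "conv_gated")


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture and training hyperparameters.

    ``hidden_channels`` and ``learning_rate`` are the two knobs worth
    searching; the rest follow the standard configuration of spatiotemporal
    LSTM video predictors.  Desk-scale runs use ``max_iterations`` <= 1000;
    the full-scale convention is tens of thousands of gradient iterations.
    """

    n_layers: int = 4
    hidden_channels: int = 32
    conv_kernel: int = 5
    patch_size: int = 4
    input_len: int = 10
    horizon: int = 10
    learning_rate: float = 3e-4
    batch_size: int = 8
    max_iterations: int = 50_000
    eval_interval: int = 100
    rng_seed: int = 0
    cell_type: str = "dual_memory"
    scheduled_sampling: bool = False
    frame_channels: int = 3
    n_val_perceptual: int = 4  # val sequences scored with the perceptual metric

    def __post_init__(self) -> None:
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd")
        if self.input_len < 1 or self.horizon < 0:
            raise ValueError("input_len >= 1 and horizon >= 0 required")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


# ------------------------------------------------------------ patch folding
def fold_patches(frames: np.ndarray, patch: int) -> np.ndarray:
    """(T, H, W, C) -> (T, C*patch*patch, H/patch, W/patch) space-to-depth."""
    t, h, w, c = frames.shape
    if h % patch or w % patch:
        raise ValueError(f"patch_size {patch} does not divide frame side {h}x{w}")
    x = frames.transpose(0, 3, 1, 2).reshape(t, c, h // patch, patch, w // patch, patch)
    x = x.transpose(0, 1, 3, 5, 2, 4)
    return x.reshape(t, c * patch * patch, h // patch, w // patch)


def unfold_patches(folded: np.ndarray, patch: int, channels: int = 3) -> np.ndarray:
    """Inverse of :func:`fold_patches`."""
    t, cpp, hp, wp = folded.shape
    x = folded.reshape(t, channels, patch, patch, hp, wp)
    x = x.transpose(0, 1, 4, 2, 5, 3).reshape(t, channels, hp * patch, wp * patch)
    return x.transpose(0, 2, 3, 1)


def persistence_forecast(video: VideoSequence, input_len: int = 10,
                         horizon: int = 10) -> VideoSequence:
    """Baseline: repeat the last observed frame for every future step."""
    if video.n_frames < input_len:
        raise ValueError("video shorter than input_len")
    last = video.frames[input_len - 1]
    frames = np.repeat(last[None], horizon, axis=0)
    return video.with_frames(frames, transform="persistence")


class _Network:
    """The layer stack + output head; owns the parameter Tensors."""

    def __init__(self, config: PredictorConfig, rng: np.random.Generator):
        self.config = config
        cin_frame = config.frame_channels * config.patch_size ** 2
        cell_cls = STLSTMCell if config.cell_type == "dual_memory" else ConvGatedCell
        self.cells = []
        for layer in range(config.n_layers):
            cin = cin_frame if layer == 0 else config.hidden_channels
            self.cells.append(cell_cls(cin, config.hidden_channels,
                                       config.conv_kernel, rng))
        scale = 1.0 / np.sqrt(config.hidden_channels)
        self.w_out = Tensor(rng.normal(0, scale, (cin_frame, config.hidden_channels, 1, 1)),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(cin_frame), requires_grad=True)

    def params(self) -> list[Tensor]:
        out = []
        for cell in self.cells:
            out.extend(cell.params())
        out.extend([self.w_out, self.b_out])
        return out

    def forward(self, batch: np.ndarray, input_len: int, horizon: int,
                gt_mask: np.ndarray | None = None) -> list[Tensor]:
        """Run the recurrence over a (N, T, C, Hp, Wp) batch.

        Observed frames are fed for the first ``input_len`` steps, the
        model's own outputs thereafter.  Returns ``horizon`` predicted
        feature maps (N, C, Hp, Wp), aligned with frames
        ``input_len .. input_len + horizon - 1``.

        ``gt_mask`` (scheduled sampling, training only): boolean per step;
        True forces the observed frame as input even past ``input_len``,
        provided the batch carries it.
        """
        cfg = self.config
        n, t_avail, c, hp, wp = batch.shape
        if t_avail < input_len:
            raise ValueError(f"need {input_len} input frames, got {t_avail}")
        zeros = lambda: Tensor(np.zeros((n, cfg.hidden_channels, hp, wp)))
        h = [zeros() for _ in self.cells]
        c_mem = [zeros() for _ in self.cells]
        m = zeros()
        preds: list[Tensor] = []
        pred: Tensor | None = None
        total_steps = input_len + horizon - 1
        for t in range(total_steps):
            if t < input_len or (gt_mask is not None and t < t_avail
                                 and gt_mask[t]):
                x = Tensor(batch[:, t])
            else:
                x = pred  # autoregressive feedback, gradients flow through
            for layer, cell in enumerate(self.cells):
                h[layer], c_mem[layer], m = cell(x, h[layer], c_mem[layer], m)
                x = h[layer]
            pred = conv2d(h[-1], self.w_out, self.b_out)
            if t + 1 >= input_len:
                preds.append(pred)
        return preds

    def get_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrays, strict=True):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch loading checkpoint")
            p.data = a.copy()


def _corpus_to_batch(sequences: list[VideoSequence], patch: int) -> np.ndarray:
    if not sequences:
        raise ValueError("empty sequence list")
    return np.stack([fold_patches(s.frames, patch) for s in sequences])


class FramePredictor:
    """Frame-prediction model over a train/validation corpus pair.

    Parameters
    ----------
    train, val
        Lists of :class:`VideoSequence` (or a :class:`VideoCorpus` whose
        train/val splits are used).  Every sequence must be at least
        ``input_len + horizon`` frames long for training.
    config
        :class:`PredictorConfig`; defaults follow the standard
        spatiotemporal-LSTM setup (4 layers of 32 channels, 5x5 kernels,
        patch 4, learning rate 3e-4).
    """

    def __init__(self, train, val=None, config: PredictorConfig | None = None):
        if isinstance(train, VideoCorpus):
            corpus = train
            train = corpus.subset("train")
            val = corpus.subset("val")
        self.config = config or PredictorConfig()
        if not train:
            raise ValueError("training set is empty")
        self.train_sequences = list(train)
        self.val_sequences = list(val or [])
        need = self.config.input_len + self.config.horizon
        for s in self.train_sequences + self.val_sequences:
            if s.n_frames < need:
                raise ValueError(
                    f"sequence {s.seq_id} has {s.n_frames} frames; "
                    f"training needs input_len + horizon = {need}")
        self._colorspace = self.train_sequences[0].colorspace

    @classmethod
    def from_corpus(cls, corpus: VideoCorpus,
                    config: PredictorConfig | None = None) -> "FramePredictor":
        return cls(corpus, config=config)

    def fit(self, max_iterations: int | None = None,
            verbose: bool = False) -> "FramePredictorResults":
        """Train by Adam on horizon-frame MSE; returns a results object.

        Fully seeded: the same ``rng_seed`` reproduces the history
        bit-for-bit.  Validation MSE (and a perceptual score on a small
        subset) is recorded every ``eval_interval`` iterations, and the
        best-validation parameters are checkpointed.
        """
        cfg = self.config
        iters = cfg.max_iterations if max_iterations is None else max_iterations
        rng = np.random.default_rng(cfg.rng_seed)
        net = _Network(cfg, rng)
        opt = Adam(net.params(), lr=cfg.learning_rate)
        train_batch_all = _corpus_to_batch(self.train_sequences, cfg.patch_size)
        val_batch = (_corpus_to_batch(self.val_sequences, cfg.patch_size)
                     if self.val_sequences else None)
        history: list[dict] = []
        best = {"val_mse": np.inf, "arrays": net.get_arrays(), "iteration": 0}

        def evaluate(iteration: int, train_mse: float | None) -> None:
            val_mse = val_perc = np.nan
            if val_batch is not None:
                val_mse = self._batch_mse(net, val_batch)
                val_perc = self._val_perceptual(net)
            history.append({"iteration": iteration, "train_mse": train_mse,
                            "val_mse": val_mse, "val_perceptual": val_perc})
            if val_batch is not None and val_mse < best["val_mse"]:
                best.update(val_mse=val_mse, arrays=net.get_arrays(),
                            iteration=iteration)
            if verbose:
                print(f"iter {iteration:6d}  train {train_mse}  val {val_mse}")

        evaluate(0, None)
        n_train = len(train_batch_all)
        for it in range(1, iters + 1):
            idx = rng.choice(n_train, size=min(cfg.batch_size, n_train),
                             replace=False)
            batch = train_batch_all[idx]
            gt_mask = None
            if cfg.scheduled_sampling:
                # linearly decaying probability of feeding the observed frame
                p_gt = max(0.0, 1.0 - it / max(iters, 1))
                gt_mask = rng.random(cfg.input_len + cfg.horizon - 1) < p_gt
            preds = net.forward(batch, cfg.input_len, cfg.horizon,
                                gt_mask=gt_mask)
            loss = None
            for k, p in enumerate(preds):
                term = (p - Tensor(batch[:, cfg.input_len + k])).mean_sq()
                loss = term if loss is None else loss + term
            loss = loss * Tensor(1.0 / max(len(preds), 1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            if it % cfg.eval_interval == 0 or it == iters:
                evaluate(it, float(loss.data))
        if val_batch is None:
            best.update(arrays=net.get_arrays(), iteration=iters)
        net.set_arrays(best["arrays"])
        return FramePredictorResults(
            config=cfg, network=net,
            history=pd.DataFrame(history),
            best_iteration=int(best["iteration"]),
            colorspace=self._colorspace,
        )

    # ------------------------------------------------------------- internals
    def _batch_mse(self, net: _Network, batch: np.ndarray) -> float:
        cfg = self.config
        preds = net.forward(batch, cfg.input_len, cfg.horizon)
        errs = [np.mean((np.clip(p.data, 0, 1) - batch[:, cfg.input_len + k]) ** 2)
                for k, p in enumerate(preds)]
        return float(np.mean(errs))

    def _val_perceptual(self, net: _Network) -> float:
        from .metrics import perceptual_score  # local import, no cycle at load
        cfg = self.config
        subset = self.val_sequences[:cfg.n_val_perceptual]
        if not subset:
            return np.nan
        scores = []
        for s in subset:
            pred = _forward_video(net, s, cfg)
            gt = s.with_frames(s.frames[cfg.input_len:cfg.input_len + cfg.horizon])
            scores.append(perceptual_score(pred, gt).mean)
        return float(np.mean(scores))


def _forward_video(net: _Network, video: VideoSequence, cfg: PredictorConfig,
                   input_len: int | None = None,
                   horizon: int | None = None) -> VideoSequence:
    input_len = cfg.input_len if input_len is None else input_len
    horizon = cfg.horizon if horizon is None else horizon
    if video.n_frames < input_len:
        raise ValueError(f"video has {video.n_frames} frames, need {input_len}")
    folded = fold_patches(video.frames, cfg.patch_size)[None]
    preds = net.forward(folded, input_len, horizon)
    if not preds:
        frames = np.zeros((0, *video.frames.shape[1:]))
    else:
        stacked = np.stack([p.data[0] for p in preds])
        frames = np.clip(unfold_patches(stacked, cfg.patch_size,
                                        cfg.frame_channels), 0.0, 1.0)
    out = VideoSequence(frames=frames, colorspace=video.colorspace,
                        frame_interval_min=video.frame_interval_min,
                        seq_id=video.seq_id,
                        lineage={"source": video.root_source,
                                 "transforms": list(video.lineage["transforms"])
                                 + ["predicted"]})
    return out


@dataclass
class FramePredictorResults:
    """Fitted predictor: learned parameters, history and prediction methods."""

    config: PredictorConfig
    network: _Network
    history: pd.DataFrame
    best_iteration: int
    colorspace: str

    def forward_sequence(self, video: VideoSequence, input_len: int | None = None,
                         horizon: int | None = None) -> VideoSequence:
        """Consume ``input_len`` observed frames, predict ``horizon`` more."""
        return _forward_video(self.network, video, self.config,
                              input_len=input_len, horizon=horizon)

    def predict(self, video: VideoSequence) -> VideoSequence:
        """Convenience wrapper over :meth:`forward_sequence`."""
        return self.forward_sequence(video)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.network.params()))

    def summary(self) -> str:
        cfg = self.config
        h = self.history
        lines = [
            "Frame Predictor Results",
            "=" * 46,
            f"cell type        {cfg.cell_type}",
            f"layers x hidden  {cfg.n_layers} x {cfg.hidden_channels}",
            f"kernel / patch   {cfg.conv_kernel} / {cfg.patch_size}",
            f"input -> horizon {cfg.input_len} -> {cfg.horizon}",
            f"learning rate    {cfg.learning_rate}",
            f"parameters       {self.n_parameters}",
            f"iterations run   {int(h['iteration'].max()) if len(h) else 0}",
            f"best iteration   {self.best_iteration}",
        ]
        if len(h) and np.isfinite(h["val_mse"].iloc[-1]):
            best_val = float(np.nanmin(h["val_mse"]))
            lines.append(f"best val MSE     {best_val:.6f} (unit pixel scale)")
        lines.append("=" * 46)
        return "\n".join(lines)

    # ---------------------------------------------------------- persistence
    def save(self, out_dir: str | Path) -> Path:
        """Self-describing checkpoint: config JSON + parameter arrays + history."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(
            {**asdict(self.config), "best_iteration": self.best_iteration,
             "colorspace": self.colorspace}, indent=2))
        arrays = {f"p{i:03d}": a for i, a in enumerate(self.network.get_arrays())}
        np.savez(out / "params.npz", **arrays)
        self.history.to_csv(out / "history.csv", index=False)
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "FramePredictorResults":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "config.json").read_text())
        best_iteration = meta.pop("best_iteration")
        colorspace = meta.pop("colorspace")
        cfg = PredictorConfig(**meta)
        net = _Network(cfg, np.random.default_rng(cfg.rng_seed))
        with np.load(in_dir / "params.npz") as npz:
            arrays = [npz[k] for k in sorted(npz.files)]
        net.set_arrays(arrays)
        history = pd.read_csv(in_dir / "history.csv")
        return cls(config=cfg, network=net, history=history,
                   best_iteration=best_iteration, colorspace=colorspace)


def grid_search(train, val, layer_sizes: list[int], learning_rates: list[float],
                budget: int = 200, base_config: PredictorConfig | None = None
                ) -> pd.DataFrame:
    """Train one reduced-budget model per (hidden, lr) pair; rank by val MSE.

    Returns a DataFrame with columns hidden_channels, learning_rate,
    val_mse, val_perceptual, sorted ascending by val_mse.
    """
    if not layer_sizes or not learning_rates:
        raise ValueError("empty grid")
    base = base_config or PredictorConfig()
    rows = []
    for hidden in layer_sizes:
        for lr in learning_rates:
            cfg = replace(base, hidden_channels=hidden, learning_rate=lr,
                          max_iterations=budget)
            res = FramePredictor(train, val, config=cfg).fit()
            tail = res.history.iloc[-1]
            rows.append({"hidden_channels": hidden, "learning_rate": lr,
                         "val_mse": float(np.nanmin(res.history["val_mse"])),
                         "val_perceptual": float(tail["val_perceptual"]),
                         "best_iteration": res.best_iteration})
    return (pd.DataFrame(rows)
            .sort_values("val_mse", ignore_index=True))
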