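"""End-to-end pipeline: simulate -> preprocess -> train -> predict -> evaluate.

One declarative YAML config drives every stage; each stage writes its
outputs and a manifest under a run directory, and the whole run is
reproducible from the global seed.  Stages are also runnable individually
for debugging (see :mod:`wellpred.cli`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .metrics import HueThresholds, compare_report
from .model import FramePredictor, FramePredictorResults, PredictorConfig
from .preprocess import AugmentSpec, preprocess_corpus
from .video import VideoCorpus, VideoSequence
from .wellsim import SimConfig, generate_corpus

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class SimSection:
    n_videos: int = 48
    grid_h: int = 24
    grid_w: int = 24
    well_radius: float = 11.0
    n_frames: int = 14
    steps_per_frame: int = 4
    seed_G: int = 3
    seed_R: int = 2
    p_div_G: float = 0.30
    p_div_R: float = 0.55
    p_kill: float = 0.05
    rare_pattern_fraction: float = 0.1
    noise_sigma: float = 0.02
    blur_sigma: float = 0.5

    def to_sim_config(self, rng_seed: int) -> SimConfig:
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)
                  if f.name != "n_videos"}
        return SimConfig(rng_seed=rng_seed, **kwargs)


@dataclass(frozen=True)
class PreprocessSection:
    keep_frames: int = 7
    crop_side: int = 24
    n_out_frames: int = 20
    out_side: int = 32
    n_test: int = 5
    target_corpus_size: int = 392
    augment_max_depth: int = 2
    augment_blur_sigma: float = 0.5
    augment_noise_sigma: float = 0.01
    train_frac: float = 0.8
    split_mode: str = "lineage"


@dataclass(frozen=True)
class MetricsSection:
    mse_scale: str = "255"
    connectivity: int = 8
    min_size: int = 1
    colony_frames: tuple[int, ...] = (11, 15, 19)


@dataclass(frozen=True)
class PipelineConfig:
    """Nested pipeline configuration; section defaults mirror each module."""

    rng_seed: int = 0
    run_id: str = "run"
    out_root: str = "runs"
    sim: SimSection = field(default_factory=SimSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    metrics: MetricsSection = field(default_factory=MetricsSection)


_SECTION_TYPES = {"sim": SimSection, "preprocess": PreprocessSection,
                  "predictor": PredictorConfig, "metrics": MetricsSection}


def _coerce(value, ftype, key: str):
    """Type-check a config value, naming the offending key on mismatch."""
    if ftype is tuple or getattr(ftype, "__origin__", None) is tuple:
        if not isinstance(value, (list, tuple)):
            raise TypeError(f"config key '{key}': expected a list, got {value!r}")
        return tuple(value)
    if ftype is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeError(f"config key '{key}': expected a number, got {value!r}")
        return float(value)
    if ftype is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise TypeError(f"config key '{key}': expected an integer, got {value!r}")
        return value
    if ftype is bool:
        if not isinstance(value, bool):
            raise TypeError(f"config key '{key}': expected a boolean, got {value!r}")
        return value
    if ftype is str:
        if not isinstance(value, str):
            raise TypeError(f"config key '{key}': expected a string, got {value!r}")
        return value
    return value


def _build_section(cls, data: dict, prefix: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        full = f"{prefix}.{key}" if prefix else key
        raise KeyError(f"unknown config key '{full}'")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        tname = f.type if isinstance(f.type, str) else getattr(f.type, "__name__", "")
        if tname.startswith("tuple"):
            ftype = tuple  # sentinel; _coerce handles sequence conversion
        else:
            ftype = {"int": int, "float": float, "str": str,
                     "bool": bool}.get(tname.split("|")[0].strip())
        full = f"{prefix}.{name}" if prefix else name
        kwargs[name] = _coerce(value, ftype, full)
    return cls(**kwargs)


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> PipelineConfig:
    """Load + schema-check a YAML config; fills defaults, rejects unknown keys."""
    if data is None:
        raw = Path(path).read_text() if path else ""
        data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise TypeError("config must be a mapping")
    top = dict(data)
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        sec = top.pop(name, {}) or {}
        if not isinstance(sec, dict):
            raise TypeError(f"config section '{name}' must be a mapping")
        sections[name] = _build_section(cls, sec, name)
    cfg = _build_section(
        PipelineConfig,
        {**top, **sections},
        "",
    )
    return cfg


def config_to_yaml(config: PipelineConfig) -> str:
    d = asdict(config)
    d["metrics"]["colony_frames"] = list(d["metrics"]["colony_frames"])
    return yaml.safe_dump(d, sort_keys=True)


# ------------------------------------------------------------------ stages
def _spawn_seeds(rng_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(rng_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def _manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()


def stage_simulate(config: PipelineConfig, run_dir: Path,
                   seed: int) -> VideoCorpus:
    sim_cfg = config.sim.to_sim_config(seed)
    corpus = generate_corpus(sim_cfg, n_videos=config.sim.n_videos,
                             rng=np.random.default_rng(seed))
    corpus_dir = run_dir / "corpus"
    for seq in corpus:
        seq.write_png_dir(corpus_dir / seq.seq_id)
    corpus.write_manifest(corpus_dir / "manifest.json")
    corpus.write_occupancy_csv(corpus_dir / "occupancy.csv")
    return corpus


def stage_preprocess(config: PipelineConfig, run_dir: Path, seed: int,
                     corpus: VideoCorpus) -> VideoCorpus:
    p = config.preprocess
    spec = AugmentSpec(target_corpus_size=p.target_corpus_size,
                       max_depth=p.augment_max_depth,
                       blur_sigma=p.augment_blur_sigma,
                       noise_sigma=p.augment_noise_sigma,
                       rng_seed=seed)
    processed = preprocess_corpus(
        corpus, spec=spec, n_test=p.n_test, keep=p.keep_frames,
        crop_side=p.crop_side, n_out_frames=p.n_out_frames,
        out_side=p.out_side, train_frac=p.train_frac,
        split_mode=p.split_mode, rng=np.random.default_rng(seed))
    processed.write_manifest(run_dir / "preprocessed" / "manifest.json")
    return processed


def stage_train(config: PipelineConfig, run_dir: Path, seed: int,
                processed: VideoCorpus) -> FramePredictorResults:
    pred_cfg = dataclasses.replace(config.predictor, rng_seed=seed)
    model = FramePredictor(processed, config=pred_cfg)
    results = model.fit()
    results.save(run_dir / "checkpoint")
    return results


def stage_predict(config: PipelineConfig, run_dir: Path,
                  results: FramePredictorResults,
                  processed: VideoCorpus) -> VideoCorpus:
    test_seqs = processed.subset("test")
    if not test_seqs:
        raise ValueError("no test sequences to predict")
    predicted = []
    for seq in test_seqs:
        pred = results.predict(seq)
        pred.write_png_dir(run_dir / "predicted" / seq.seq_id)
        predicted.append(pred)
    corpus = VideoCorpus(sequences=predicted)
    corpus.write_manifest(run_dir / "predicted" / "manifest.json")
    return corpus


def stage_evaluate(config: PipelineConfig, run_dir: Path,
                   processed: VideoCorpus, predicted: VideoCorpus) -> dict:
    gt = VideoCorpus(sequences=list(processed.subset("test")))
    return compare_report(gt, predicted, run_dir / "report",
                          mse_scale=config.metrics.mse_scale,
                          colony_frames=tuple(config.metrics.colony_frames),
                          input_len=config.predictor.input_len)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage; partial
    outputs written so far are preserved.
    """
    run_dir = Path(config.out_root) / config.run_id
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(config_to_yaml(config))
    seeds = _spawn_seeds(config.rng_seed, 4)
    logger.info("run %s: stage seeds %s", config.run_id, seeds)
    timings = {}
    state: dict = {}

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            state[name] = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", name, timings[name])

    run_stage("simulate", lambda: stage_simulate(config, run_dir, seeds[0]))
    run_stage("preprocess", lambda: stage_preprocess(
        config, run_dir, seeds[1], state["simulate"]))
    run_stage("train", lambda: stage_train(
        config, run_dir, seeds[2], state["preprocess"]))
    run_stage("predict", lambda: stage_predict(
        config, run_dir, state["train"], state["preprocess"]))
    run_stage("evaluate", lambda: stage_evaluate(
        config, run_dir, state["preprocess"], state["predict"]))

    manifest = {
        "run_id": config.run_id,
        "wellpred_version": __version__,
        "rng_seed": config.rng_seed,
        "stage_seeds": seeds,
        "timings_s": timings,
        "corpus_manifest_sha256": _manifest_hash(state["simulate"].manifest()),
        "preprocessed_manifest_sha256": _manifest_hash(
            state["preprocess"].manifest()),
        "mean_mse": state["evaluate"]["mean_mse"],
        "mean_perceptual": state["evaluate"]["mean_perceptual"],
    }
    (run_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return run_dir
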