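"""Pipeline orchestration: reproducible staged commands over a work dir.

Stages (each idempotent given identical config + seed):

    synth -> sample -> train-tiles -> infer -> train-rnn -> classify -> evaluate

Every stage logs its parameters and seed to ``run_manifest.jsonl`` in the
work dir and fails with a :class:`MissingArtifactError` naming the
producing command when an upstream artefact is absent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .aggregate import (
    RnnAggregator,
    RnnConfig,
    aggregate_max_pool,
    aggregate_rnn,
    train_rnn_aggregator,
    write_predictions,
)
from .augment import AugmentConfig
from .backbones import BackboneConfig, load_model, save_model
from .inference import (
    extract_features,
    load_features,
    load_grid,
    predict_slide,
    render_argmax_overlay,
    render_heatmap,
    save_features,
    save_grid,
)
from .labels import LABELS
from .preprocess import (
    detect_tissue,
    read_tile_manifest,
    sample_training_tiles,
    write_tile_manifest,
)
from .stats import TARGET_LABELS, evaluate_aggregators, save_report
from .synthetic import SyntheticSpec, generate_cohort, read_cohort
from .training import TrainConfig, train_tile_classifier

log = logging.getLogger(__name__)


class MissingArtifactError(FileNotFoundError):
    """An upstream stage has not produced a required file yet."""

    def __init__(self, path: Path, producer: str):
        super().__init__(
            f"missing artefact {path}; run `wsitile {producer}` first"
        )
        self.path = path
        self.producer = producer


@dataclass(frozen=True)
class PreprocessConfig:
    saturation_threshold: float = 0.07
    mask_downsample: int = 32
    tile_size: int = 512
    central_window: int = 128
    n_per_label: int = 400
    min_coverage: float = 0.5


@dataclass(frozen=True)
class EvalConfig:
    n_boot: int = 1000
    threshold: float = 0.5


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration for a full run.

    Defaults carry the reference operating points (512 px tiles, 128 px
    centred window, 400 tiles per label, stride 256, 1000 bootstrap
    iterations, threshold 0.5, full-scale training schedule);
    :meth:`desk_scale` swaps in the CPU-scale synthetic-experiment sizes.
    """

    work_dir: str = "wsitile_run"
    seed: int = 0
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    n_train_per_label: dict = field(default_factory=lambda: {l: 10 for l in LABELS})
    n_test_per_label: dict = field(default_factory=lambda: {l: 5 for l in LABELS})
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    stride: int = 256
    heatmap_stride: int = 128
    rnn: RnnConfig = field(default_factory=RnnConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    @classmethod
    def desk_scale(cls, work_dir: str, seed: int = 0) -> "PipelineConfig":
        """The synthetic-cohort study conditions at CPU scale.

        30 training and 15 test slides (balanced over the three labels),
        64 tiles per label per slide, 400 optimisation iterations at batch
        32 for the tiny CNN, and the reference recurrent-aggregator
        schedule. Colour jitter without geometric rescaling (the sampler's
        random origins and orientations already provide geometric variety).
        """
        return cls(
            work_dir=work_dir,
            seed=seed,
            synthetic=replace(SyntheticSpec(), seed=seed),
            preprocess=PreprocessConfig(n_per_label=64),
            train=TrainConfig(
                batch_size=32,
                total_iterations=400,
                val_check_every=40,
                seed=seed,
            ),
            augment=AugmentConfig(scale_jitter=0.0, position_offset_px=0),
            backbone=replace(BackboneConfig(), seed=seed),
            rnn=replace(RnnConfig(), seed=seed),
        )

    # -- layout -------------------------------------------------------------

    @property
    def paths(self) -> dict:
        root = Path(self.work_dir)
        return {
            "root": root,
            "cohort": root / "cohort",
            "manifest": root / "cohort" / "cohort.csv",
            "tiles": root / "tiles.csv",
            "model": root / "model" / "tile_model",
            "train_log": root / "model" / "training_log.csv",
            "inference": root / "inference",
            "heatmaps": root / "heatmaps",
            "rnn": root / "model" / "rnn_model",
            "rnn_log": root / "model" / "rnn_log.csv",
            "pred_mp": root / "predictions_mp.csv",
            "pred_rnn": root / "predictions_rnn.csv",
            "report": root / "eval_report",
        }

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("synthetic", SyntheticSpec),
            ("preprocess", PreprocessConfig),
            ("backbone", BackboneConfig),
            ("train", TrainConfig),
            ("augment", AugmentConfig),
            ("rnn", RnnConfig),
            ("eval", EvalConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = kwargs[key]
                if key == "synthetic" and "texture_params" in sub_kwargs:
                    from .synthetic import TextureParams

                    sub_kwargs["texture_params"] = {
                        k: TextureParams(**v) if isinstance(v, dict) else v
                        for k, v in sub_kwargs["texture_params"].items()
                    }
                if key == "synthetic" and "region_radius_px" in sub_kwargs:
                    sub_kwargs["region_radius_px"] = tuple(sub_kwargs["region_radius_px"])
                kwargs[key] = sub(**sub_kwargs)
        return cls(**kwargs)


def _log_run(config: PipelineConfig, command: str) -> None:
    root = Path(config.work_dir)
    root.mkdir(parents=True, exist_ok=True)
    entry = {
        "command": command,
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
    }
    with open(root / "run_manifest.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    config.to_yaml(root / "resolved_config.yaml")


def _require(path: Path, producer: str) -> Path:
    if not Path(path).exists():
        raise MissingArtifactError(path, producer)
    return path


def _load_cohort(config: PipelineConfig) -> list:
    manifest = _require(config.paths["manifest"], "synth")
    return read_cohort(manifest)


# -- commands ---------------------------------------------------------------


def cmd_synth(config: PipelineConfig) -> list:
    """Generate the synthetic cohort into the work dir."""
    _log_run(config, "synth")
    records, manifest = generate_cohort(
        config.synthetic,
        config.n_train_per_label,
        config.n_test_per_label,
        config.paths["cohort"],
    )
    log.info("generated %d slides -> %s", len(records), manifest)
    return records


def cmd_sample(config: PipelineConfig) -> dict:
    """Sample balanced training tiles from the train-split slides."""
    _log_run(config, "sample")
    pp = config.preprocess
    records = _load_cohort(config)
    tiles_by_slide = {}
    all_tiles, all_ids = [], []
    for record in records:
        if record.split != "train":
            continue
        image = record.load_image()
        mask = detect_tissue(image, pp.saturation_threshold, pp.mask_downsample)
        tiles = sample_training_tiles(
            record,
            mask,
            n_per_label=pp.n_per_label,
            tile_size=pp.tile_size,
            central_window=pp.central_window,
            min_coverage=pp.min_coverage,
            rng_seed=config.seed + hash_seed(record.slide_id),
        )
        tiles_by_slide[record.slide_id] = tiles
        all_tiles.extend(tiles)
        all_ids.extend([record.slide_id] * len(tiles))
        del image
    write_tile_manifest(all_tiles, config.paths["tiles"], all_ids)
    log.info("sampled %d tiles from %d slides", len(all_tiles), len(tiles_by_slide))
    return tiles_by_slide


def hash_seed(text: str) -> int:
    """Stable small-integer seed offset from a string."""
    import zlib

    return zlib.crc32(text.encode()) % 100_000


def cmd_train_tiles(config: PipelineConfig):
    """Train the tile classifier on the sampled tile manifest."""
    _log_run(config, "train-tiles")
    records = {r.slide_id: r for r in _load_cohort(config)}
    manifest = _require(config.paths["tiles"], "sample")
    tiles_by_slide: dict = {}
    for sid, tile in read_tile_manifest(manifest):
        tiles_by_slide.setdefault(sid, []).append(tile)
    model, train_log = train_tile_classifier(
        records, tiles_by_slide, config.backbone, config.train, config.augment
    )
    config.paths["model"].parent.mkdir(parents=True, exist_ok=True)
    save_model(model, config.paths["model"])
    train_log.to_csv(config.paths["train_log"], index=False)
    log.info(
        "trained tile model; best validation loss %.4f",
        train_log.attrs["best_val_loss"],
    )
    return model, train_log


def cmd_infer(config: PipelineConfig, heatmaps: bool = True) -> None:
    """Sliding-window inference: grids, feature sequences, heatmaps."""
    _log_run(config, "infer")
    _require(config.paths["model"].with_suffix(".npz"), "train-tiles")
    model = load_model(config.paths["model"])
    pp = config.preprocess
    records = _load_cohort(config)
    out = config.paths["inference"]
    out.mkdir(parents=True, exist_ok=True)
    hm_dir = config.paths["heatmaps"]
    if heatmaps:
        hm_dir.mkdir(parents=True, exist_ok=True)
    for record in records:
        image = record.load_image()
        mask = detect_tissue(image, pp.saturation_threshold, pp.mask_downsample)
        grid = predict_slide(model, record, mask=mask, stride=config.stride)
        save_grid(grid, out / f"{record.slide_id}_grid")
        seq = extract_features(model, record, mask=mask, stride=config.stride)
        save_features(seq, out / f"{record.slide_id}_features")
        if heatmaps:
            for label in TARGET_LABELS:
                Image.fromarray(render_heatmap(grid, label)).save(
                    hm_dir / f"{record.slide_id}_{label}.png"
                )
            Image.fromarray(render_argmax_overlay(grid, image)).save(
                hm_dir / f"{record.slide_id}_overlay.png"
            )
        del image
    log.info("inference complete for %d slides", len(records))


def cmd_train_rnn(config: PipelineConfig):
    """Train the recurrent aggregator on train-split feature sequences."""
    _log_run(config, "train-rnn")
    records = _load_cohort(config)
    sequences, labels = [], {}
    for record in records:
        if record.split != "train":
            continue
        path = config.paths["inference"] / f"{record.slide_id}_features"
        _require(path.with_suffix(".npz"), "infer")
        sequences.append(load_features(path))
        labels[record.slide_id] = record.slide_label
    model, rnn_log = train_rnn_aggregator(sequences, labels, config.rnn)
    _save_rnn(model, config.paths["rnn"])
    rnn_log.to_csv(config.paths["rnn_log"], index=False)
    log.info(
        "trained recurrent aggregator; best validation loss %.4f",
        rnn_log.attrs["best_val_loss"],
    )
    return model, rnn_log


def _save_rnn(model: RnnAggregator, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    arrays["mu"] = model.mu
    arrays["sigma"] = model.sigma
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(
        json.dumps({"feature_dim": model.feature_dim, "config": asdict(model.cfg)})
    )


def load_rnn(path: Path) -> RnnAggregator:
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    model = RnnAggregator(meta["feature_dim"], RnnConfig(**meta["config"]))
    data = np.load(Path(path).with_suffix(".npz"))
    for i, p in enumerate(model.params):
        p.value[...] = data[f"p{i}"]
    model.mu = data["mu"]
    model.sigma = data["sigma"]
    return model


def cmd_classify(config: PipelineConfig, aggregator: str) -> pd.DataFrame:
    """Slide-level predictions with one aggregator -> CSV."""
    if aggregator not in ("mp", "rnn"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    _log_run(config, f"classify-{aggregator}")
    records = _load_cohort(config)
    predictions = []
    if aggregator == "rnn":
        _require(config.paths["rnn"].with_suffix(".npz"), "train-rnn")
        rnn = load_rnn(config.paths["rnn"])
    for record in records:
        if aggregator == "mp":
            path = config.paths["inference"] / f"{record.slide_id}_grid"
            _require(path.with_suffix(".npz"), "infer")
            grid = load_grid(path)
            pred = aggregate_max_pool(grid)
            pred.slide_id = record.slide_id
        else:
            path = config.paths["inference"] / f"{record.slide_id}_features"
            _require(path.with_suffix(".npz"), "infer")
            pred = aggregate_rnn(rnn, load_features(path))
        predictions.append(pred)
    out = config.paths[f"pred_{aggregator}"]
    write_predictions(predictions, out)
    log.info("wrote %d %s-aggr predictions -> %s", len(predictions), aggregator, out)
    return pd.read_csv(out)


def cmd_evaluate(config: PipelineConfig) -> dict:
    """Compare MP-aggr and RNN-aggr on the test split -> EvalReport."""
    _log_run(config, "evaluate")
    records = {r.slide_id: r for r in _load_cohort(config)}
    test_ids = [sid for sid, r in records.items() if r.split == "test"]
    tables = {}
    for aggregator in ("mp", "rnn"):
        path = _require(config.paths[f"pred_{aggregator}"], f"classify {aggregator}")
        df = pd.read_csv(path)
        df = df[df["slide_id"].isin(test_ids)].reset_index(drop=True)
        df = df.sort_values("slide_id").reset_index(drop=True)
        df["true_label"] = [records[s].slide_label for s in df["slide_id"]]
        tables[aggregator] = df
    report = evaluate_aggregators(
        tables["mp"],
        tables["rnn"],
        n_boot=config.eval.n_boot,
        threshold=config.eval.threshold,
        seed=config.seed,
    )
    save_report(report, config.paths["report"])
    log.info("evaluation report -> %s", config.paths["report"])
    return report


def run_full_pipeline(config: PipelineConfig) -> dict:
    """synth -> sample -> train-tiles -> infer -> train-rnn -> classify x2 -> evaluate."""
    cmd_synth(config)
    cmd_sample(config)
    cmd_train_tiles(config)
    cmd_infer(config, heatmaps=False)
    cmd_train_rnn(config)
    cmd_classify(config, "mp")
    cmd_classify(config, "rnn")
    return cmd_evaluate(config)
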