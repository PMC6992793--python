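"""Tile-classifier training.

Weighted cross-entropy minimisation with an adaptive-moment optimiser, a
warm-started decaying learning-rate schedule, slide-level (never tile-
level) stratified validation hold-out, and minimum-validation-loss
checkpoint selection.

The reference full-scale configuration (batch 128, 625K iterations,
learning rate warming from 0.001 to 0.05) is expressed by the defaults;
desk-scale experiments override ``total_iterations`` and ``batch_size``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment
from .backbones import BackboneConfig, TinyCNN, build_backbone, normalize_pixels
from .labels import LABELS
from .nn import AdaMoment, softmax_xent
from .preprocess import extract_tile_pixels

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    total_iterations: int = 625_000
    optimizer: str = "adam"  # or "rmsprop"; the moment scalars apply to both
    momentum: float = 0.9
    decay: float = 0.9
    epsilon: float = 1.0
    lr_min_start: float = 0.001
    lr_max: float = 0.05
    warmup_fraction: float = 0.05
    lr_decay_factor: float = 0.94
    lr_decay_every_fraction: float = 0.02
    validation_fraction: float = 0.05
    val_check_every: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.lr_min_start <= self.lr_max:
            raise ValueError("need 0 < lr_min_start <= lr_max")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.total_iterations < 1:
            raise ValueError("batch_size and total_iterations must be >= 1")


def learning_rate(iteration: int, cfg: TrainConfig) -> float:
    """Warm start: linear ramp lr_min_start -> lr_max over the first
    ``warmup_fraction`` of iterations, then stepwise exponential decay
    (``lr_decay_factor`` every ``lr_decay_every_fraction`` of the run)."""
    warmup = max(1, int(round(cfg.warmup_fraction * cfg.total_iterations)))
    if iteration < warmup:
        t = iteration / warmup
        return cfg.lr_min_start + t * (cfg.lr_max - cfg.lr_min_start)
    every = max(1, int(round(cfg.lr_decay_every_fraction * cfg.total_iterations)))
    steps = (iteration - warmup) // every
    return cfg.lr_max * cfg.lr_decay_factor**steps


def compute_label_weights(slide_label_counts: dict) -> dict:
    """Inverse-frequency class weights, normalised to mean 1.

    Labels with zero count get weight 0; at least one count must be
    positive. Balanced counts give all weights exactly 1.
    """
    if any(c < 0 for c in slide_label_counts.values()):
        raise ValueError("counts must be non-negative")
    present = {k: c for k, c in slide_label_counts.items() if c > 0}
    if not present:
        raise ValueError("all label counts are zero")
    # scale by the smallest count so balanced counts give exactly 1.0
    c_min = min(present.values())
    inv = {k: c_min / c for k, c in present.items()}
    mean_inv = sum(inv.values()) / len(inv)
    weights = {k: 0.0 for k in slide_label_counts}
    weights.update({k: v / mean_inv for k, v in inv.items()})
    return weights


def split_validation_slides(
    slide_labels: dict, fraction: float, rng: np.random.Generator
) -> tuple[list, list]:
    """Hold out a fraction of *slides*, stratified by slide label."""
    if len(slide_labels) < 2:
        raise ValueError("need at least 2 slides to form a validation split")
    by_label: dict[str, list] = {}
    for sid in sorted(slide_labels):
        by_label.setdefault(slide_labels[sid], []).append(sid)
    train_ids, val_ids = [], []
    for label in sorted(by_label):
        ids = by_label[label]
        rng.shuffle(ids)
        k = int(fraction * len(ids) + 0.5)  # round half up, per stratum
        val_ids.extend(ids[:k])
        train_ids.extend(ids[k:])
    if not val_ids:  # fraction too small for every stratum: take one slide
        val_ids.append(train_ids.pop())
    if not train_ids:
        raise ValueError("validation split consumed every slide")
    return sorted(train_ids), sorted(val_ids)


def build_tile_dataset(
    records: dict,
    tiles_by_slide: dict,
    model: TinyCNN,
    augment_cfg: AugmentConfig | None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract, augment once, normalise and pool every manifest tile.

    Returns (pooled float32 (N,g,g,3), labels int64, slide index int64).
    Colour augmentation is applied here, once per tile, on the pooled
    grid (global colour shifts commute with block averaging to within
    quantisation); the cheap exact transforms (dihedral flips,
    brightness/contrast) are re-randomised every iteration inside the
    training loop.
    """
    xs, ys, sids = [], [], []
    slide_order = sorted(tiles_by_slide)
    label_to_idx = {lab: i for i, lab in enumerate(LABELS)}
    f = model.pool_factor
    for s_idx, sid in enumerate(slide_order):
        record = records[sid]
        image = record.load_image()
        rng = np.random.default_rng(np.random.SeedSequence([seed, s_idx]))
        static_cfg = (
            augment_cfg.color_only() if augment_cfg is not None else None
        )
        for tile in tiles_by_slide[sid]:
            px = extract_tile_pixels(image, tile)
            if f > 1:
                g = px.shape[0] // f
                px = px.reshape(g, f, g, f, 3).mean(axis=(1, 3))
                px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
            if static_cfg is not None:
                px = augment(px, static_cfg, rng)
            xs.append(normalize_pixels(px))
            ys.append(label_to_idx[tile.label])
            sids.append(s_idx)
        del image
    if not xs:
        raise ValueError("empty tile manifest")
    return (
        np.stack(xs).astype(np.float32),
        np.asarray(ys, dtype=np.int64),
        np.asarray(sids, dtype=np.int64),
    )


def _batch_augment(x: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-iteration exact transforms on pooled tiles.

    Dihedral flips/rotations and brightness/contrast jitter commute with
    the backbone's block-average input pooling, so applying them on the
    pooled grid is equivalent to applying them on the raw tile.
    """
    out = x.copy()
    n = out.shape[0]
    if cfg.rotate_quarter:
        for k in range(1, 4):
            pick = rng.random(n) < 0.25
            out[pick] = np.rot90(out[pick], k, axes=(1, 2))
    if cfg.flip:
        pick = rng.random(n) < 0.5
        out[pick] = out[pick, :, ::-1]
        pick = rng.random(n) < 0.5
        out[pick] = out[pick, ::-1, :]
    if cfg.contrast > 0:
        c = rng.uniform(1 - cfg.contrast, 1 + cfg.contrast, size=(n, 1, 1, 1)).astype(np.float32)
        mean = out.mean(axis=(1, 2, 3), keepdims=True)
        out = (out - mean) * c + mean
    if cfg.brightness > 0:
        # pixel range is [-1, 1], so a brightness fraction maps to 2x offset
        b = rng.uniform(-cfg.brightness, cfg.brightness, size=(n, 1, 1, 1)).astype(np.float32)
        out = out + 2.0 * b
    return np.clip(out, -1.0, 1.0)


def train_tile_classifier(
    records: dict,
    tiles_by_slide: dict,
    backbone_cfg: BackboneConfig,
    train_cfg: TrainConfig,
    augment_cfg: AugmentConfig | None = None,
) -> tuple[TinyCNN, pd.DataFrame]:
    """Train the tile classifier and return (best checkpoint, log).

    ``records``: slide_id -> SlideRecord; ``tiles_by_slide``: slide_id ->
    list of labelled TileRefs. A ``validation_fraction`` of slides
    (stratified by slide label) is held out; the checkpoint with the
    lowest validation loss wins.
    """
    train_cfg.validate()
    if not tiles_by_slide or all(not t for t in tiles_by_slide.values()):
        raise ValueError("empty tile manifest")
    tile_labels = {t.label for tiles in tiles_by_slide.values() for t in tiles}
    if len(tile_labels) < 2:
        raise ValueError("need tiles of at least 2 labels to train")

    rng = np.random.default_rng(train_cfg.seed)
    slide_labels = {sid: records[sid].slide_label for sid in tiles_by_slide}
    train_ids, val_ids = split_validation_slides(
        slide_labels, train_cfg.validation_fraction, rng
    )
    model = build_backbone(backbone_cfg)
    if not isinstance(model, TinyCNN):
        raise ValueError("only the tiny_cnn family is trainable on CPU")

    def subset(ids):
        recs = {sid: records[sid] for sid in ids}
        tiles = {sid: tiles_by_slide[sid] for sid in ids}
        return recs, tiles

    x_train, y_train, _ = build_tile_dataset(
        *subset(train_ids), model, augment_cfg, seed=train_cfg.seed
    )
    x_val, y_val, _ = build_tile_dataset(*subset(val_ids), model, None, seed=train_cfg.seed)

    counts = {lab: int((y_train == i).sum()) for i, lab in enumerate(LABELS)}
    weights = compute_label_weights(counts)
    weight_vec = np.array([weights[lab] for lab in LABELS], dtype=np.float32)
    log.info("label weights %s from tile counts %s", weights, counts)

    opt = AdaMoment(
        model.params,
        momentum=train_cfg.momentum,
        decay=train_cfg.decay,
        epsilon=train_cfg.epsilon,
        mode=train_cfg.optimizer,
    )
    val_every = train_cfg.val_check_every or max(1, train_cfg.total_iterations // 20)
    best = (np.inf, None)
    rows = []
    n = x_train.shape[0]
    for it in range(train_cfg.total_iterations):
        lr = learning_rate(it, train_cfg)
        opt.lr = lr
        idx = rng.integers(0, n, size=min(train_cfg.batch_size, n))
        xb = x_train[idx]
        if augment_cfg is not None:
            xb = _batch_augment(xb, augment_cfg, rng)
        yb = y_train[idx]
        opt.zero_grad()
        _, _, logits = model.forward_pooled(xb, train=True)
        loss, dlogits = softmax_xent(logits, yb, weight_vec[yb])
        model.backward(dlogits)
        opt.step()
        val_loss = np.nan
        if (it + 1) % val_every == 0 or it == train_cfg.total_iterations - 1:
            val_loss = _validation_loss(model, x_val, y_val, weight_vec)
            if val_loss < best[0]:
                best = (val_loss, [p.value.copy() for p in model.params])
        rows.append((it, lr, loss, val_loss))
    if best[1] is not None:
        for p, v in zip(model.params, best[1]):
            p.value[...] = v
    train_log = pd.DataFrame(rows, columns=["iteration", "lr", "train_loss", "val_loss"])
    train_log.attrs["best_val_loss"] = best[0]
    train_log.attrs["val_slides"] = val_ids
    return model, train_log


def _validation_loss(model, x_val, y_val, weight_vec, chunk: int = 256) -> float:
    total, count = 0.0, 0
    for lo in range(0, x_val.shape[0], chunk):
        xb, yb = x_val[lo : lo + chunk], y_val[lo : lo + chunk]
        _, _, logits = model.forward_pooled(xb, train=False)
        loss, _ = softmax_xent(logits, yb, weight_vec[yb])
        total += loss * len(yb)
        count += len(yb)
    return total / max(count, 1)
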