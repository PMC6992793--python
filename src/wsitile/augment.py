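"""Training-time tile augmentation.

Random flips and rotations (tissue has no canonical orientation), minor
scale jitter, minor position offsets, hue/saturation offsets, and
brightness/contrast perturbations. All magnitudes are configurable; an
identity config returns the input bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize, rotate


@dataclass(frozen=True)
class AugmentConfig:
    flip: bool = True
    rotate_quarter: bool = True
    rotation_deg: float = 0.0  # optional free-angle rotation, +/- this many degrees
    scale_jitter: float = 0.10
    position_offset_px: int = 16
    hue_offset: float = 0.05
    saturation_offset: float = 0.20
    brightness: float = 0.20
    contrast: float = 0.20
    seed: int = 0

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(
            flip=False,
            rotate_quarter=False,
            rotation_deg=0.0,
            scale_jitter=0.0,
            position_offset_px=0,
            hue_offset=0.0,
            saturation_offset=0.0,
            brightness=0.0,
            contrast=0.0,
        )

    def geometric_only(self) -> "AugmentConfig":
        return replace(self, hue_offset=0.0, saturation_offset=0.0, brightness=0.0, contrast=0.0)

    def color_only(self) -> "AugmentConfig":
        return replace(
            self, flip=False, rotate_quarter=False, rotation_deg=0.0,
            scale_jitter=0.0, position_offset_px=0,
        )


def _to_uint8(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def augment(tile: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomised composition of the configured transforms on a uint8 tile."""
    out = tile
    side = out.shape[0]

    if cfg.flip:
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
    if cfg.rotate_quarter:
        out = np.rot90(out, int(rng.integers(4)))
    if cfg.rotation_deg > 0:
        angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
        out = _to_uint8(rotate(out.astype(np.float64), angle, mode="reflect", order=1))
    if cfg.scale_jitter > 0:
        out = _scale(out, 1.0 + float(rng.uniform(-cfg.scale_jitter, cfg.scale_jitter)), side)
    if cfg.position_offset_px > 0:
        dx = int(rng.integers(-cfg.position_offset_px, cfg.position_offset_px + 1))
        dy = int(rng.integers(-cfg.position_offset_px, cfg.position_offset_px + 1))
        out = _shift(out, dx, dy)

    color = (
        cfg.hue_offset > 0
        or cfg.saturation_offset > 0
        or cfg.brightness > 0
        or cfg.contrast > 0
    )
    if color:
        x = out.astype(np.float64)
        if cfg.hue_offset > 0 or cfg.saturation_offset > 0:
            hsv = rgb2hsv(x / 255.0)
            hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-cfg.hue_offset, cfg.hue_offset), 1.0)
            hsv[..., 1] = np.clip(
                hsv[..., 1] + rng.uniform(-cfg.saturation_offset, cfg.saturation_offset), 0.0, 1.0
            )
            x = hsv2rgb(hsv) * 255.0
        if cfg.contrast > 0:
            c = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
            mean = x.mean(axis=(0, 1), keepdims=True)
            x = (x - mean) * c + mean
        if cfg.brightness > 0:
            x = x + rng.uniform(-cfg.brightness, cfg.brightness) * 255.0
        out = _to_uint8(x)

    return np.ascontiguousarray(out)


def apply_hue_offset(tile: np.ndarray, delta: float) -> np.ndarray:
    """Deterministic hue rotation (helper for round-trip checks)."""
    hsv = rgb2hsv(tile.astype(np.float64) / 255.0)
    hsv[..., 0] = np.mod(hsv[..., 0] + delta, 1.0)
    return _to_uint8(hsv2rgb(hsv) * 255.0)


def _scale(tile: np.ndarray, factor: float, side: int) -> np.ndarray:
    """Zoom by cropping (in) or shrinking with reflect padding (out)."""
    if abs(factor - 1.0) < 1e-9:
        return tile
    if factor > 1.0:
        crop = max(2, int(round(side / factor)))
        o = (side - crop) // 2
        patch = tile[o : o + crop, o : o + crop]
        return _to_uint8(resize(patch.astype(np.float64), (side, side, 3), order=1, mode="reflect"))
    small = max(2, int(round(side * factor)))
    shrunk = _to_uint8(resize(tile.astype(np.float64), (small, small, 3), order=1, mode="reflect"))
    pad = side - small
    lo = pad // 2
    return np.pad(shrunk, ((lo, pad - lo), (lo, pad - lo), (0, 0)), mode="reflect")


def _shift(tile: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate with reflect padding (no wraparound)."""
    if dx == 0 and dy == 0:
        return tile
    m = max(abs(dx), abs(dy))
    padded = np.pad(tile, ((m, m), (m, m), (0, 0)), mode="reflect")
    side = tile.shape[0]
    return padded[m + dy : m + dy + side, m + dx : m + dx + side]
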