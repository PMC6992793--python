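"""Deterministic synthetic whole-slide cohorts.

Generates slide-scale RGB TIFFs with a white, low-saturation background and
saturated, procedurally textured tissue blobs — one texture per diagnostic
label — together with matching polygon annotations (GeoJSON) and a cohort
manifest CSV. The statistical structure mirrors what the pipeline assumes
of scanned H&E biopsies: tissue is separable from background by saturation
thresholding, each annotated region carries one label, and textures are
separable by a small classifier yet non-constant within a tile.

A slide may additionally carry one small *false-positive speck*: a tiny
off-label textured disc placed on the background, away from every annotated
region. Specks are too small and too far from annotations to enter training
tiles, but sliding-window inference sees them — they are the controlled
mechanism for studying how slide-level aggregation reacts to isolated
false-positive tiles.

Determinism: all output is a pure function of (spec, slide_id); the
per-slide RNG is seeded from ``spec.seed`` and a CRC32 of the slide id.
"""

from __future__ import annotations

import csv
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image, ImageDraw
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, mapping, shape
from skimage.color import hsv2rgb

from .labels import ADENOCARCINOMA, ADENOMA, LABELS, NON_NEOPLASTIC, check_label

log = logging.getLogger(__name__)

#: Default tissue-detection saturation threshold the textures must clear.
DEFAULT_SATURATION_THRESHOLD = 0.07


class PlacementError(RuntimeError):
    """Requested regions could not be placed without overlap."""


@dataclass(frozen=True)
class TextureParams:
    """Band-limited noise texture for one label.

    base_hue: HSV hue centre in [0, 1).
    saturation: HSV saturation level in [0, 1]; must sit well above the
        tissue-detection threshold (background is near zero saturation).
    spatial_freq: characteristic frequency of the noise field, cycles/px.
    """

    base_hue: float
    saturation: float
    spatial_freq: float


#: Widely separated hues so textures are trivially separable by a small CNN.
DEFAULT_TEXTURES = {
    ADENOCARCINOMA: TextureParams(base_hue=0.83, saturation=0.65, spatial_freq=1 / 24),
    ADENOMA: TextureParams(base_hue=0.08, saturation=0.60, spatial_freq=1 / 32),
    NON_NEOPLASTIC: TextureParams(base_hue=0.42, saturation=0.55, spatial_freq=1 / 48),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic slide / cohort.

    Defaults define the reference study conditions: 4096x3072 px slides
    (room for well over 100 stride-256 window positions), one region of the
    slide's own label plus one non-neoplastic region per slide, and a 50%
    chance of one 96 px off-label speck on the background.
    """

    slide_width_px: int = 4096
    slide_height_px: int = 3072
    n_regions_per_label: dict = field(
        default_factory=lambda: {ADENOCARCINOMA: 1, ADENOMA: 1, NON_NEOPLASTIC: 1}
    )
    region_radius_px: tuple = (350, 520)
    texture_params: dict = field(default_factory=lambda: dict(DEFAULT_TEXTURES))
    false_positive_speck_rate: float = 0.5
    speck_diameter_px: int = 96
    speck_clearance_px: int = 384
    seed: int = 0

    def validate(self) -> None:
        if self.slide_width_px < 1024 or self.slide_height_px < 1024:
            raise ValueError("slide dimensions must be >= 1024 px in each axis")
        lo, hi = self.region_radius_px
        if not (0 < lo <= hi):
            raise ValueError(f"bad region radius range {self.region_radius_px}")
        if not 0.0 <= self.false_positive_speck_rate <= 1.0:
            raise ValueError("false_positive_speck_rate must be in [0, 1]")
        for label, n in self.n_regions_per_label.items():
            check_label(label)
            if n < 0:
                raise ValueError(f"negative region count for {label}")
        for label, tex in self.texture_params.items():
            check_label(label)
            # noise amplitude on saturation is 0.08; keep a strict margin
            if tex.saturation - 0.10 <= DEFAULT_SATURATION_THRESHOLD:
                raise ValueError(
                    f"texture saturation for {label} too close to the "
                    f"tissue-detection threshold {DEFAULT_SATURATION_THRESHOLD}"
                )


@dataclass
class SlideRecord:
    """One slide: image reference, geometry, annotations, diagnosis."""

    slide_id: str
    image_uri: Path
    width_px: int
    height_px: int
    magnification_tag: str = "20X"
    #: list of (shapely Polygon in level-0 px, label)
    regions: list = field(default_factory=list)
    #: false-positive specks, kept separate from diagnostic annotations
    specks: list = field(default_factory=list)
    slide_label: str | None = None
    split: str = ""

    @property
    def annotation_uri(self) -> Path:
        return Path(self.image_uri).with_suffix(".geojson")

    def region_labels(self) -> set:
        return {label for _, label in self.regions}

    def load_image(self, mode: str = "memmap") -> np.ndarray:
        """Level-0 RGB pixels; 'memmap' avoids loading the full slide."""
        if mode == "memmap":
            try:
                return tifffile.memmap(self.image_uri)
            except ValueError:  # non-contiguous file; fall back
                pass
        return tifffile.imread(self.image_uri)


def _slide_rng(spec: SyntheticSpec, slide_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, zlib.crc32(slide_id.encode())])
    )


def _blob_polygon(
    rng: np.random.Generator, cx: float, cy: float, radius: float, n_vertices: int = 96
) -> Polygon:
    """Closed blob outline: a circle with smooth radial perturbation."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, 1.0)
    for k in (2, 3, 5):
        amp = rng.uniform(0.0, 0.09)
        phase = rng.uniform(0.0, 2 * np.pi)
        r += amp * np.sin(k * theta + phase)
    xs = cx + radius * r * np.cos(theta)
    ys = cy + radius * r * np.sin(theta)
    return Polygon(np.column_stack([xs, ys]))


def _texture_rgb(
    rng: np.random.Generator, height: int, width: int, tex: TextureParams
) -> np.ndarray:
    """Band-limited HSV noise mapped to 8-bit RGB."""
    sigma = max(1.0, 1.0 / (2.0 * np.pi * tex.spatial_freq))

    def _field() -> np.ndarray:
        f = gaussian_filter(rng.standard_normal((height, width)), sigma, mode="reflect")
        sd = f.std()
        return f / sd if sd > 0 else f

    hue = np.mod(tex.base_hue + 0.02 * _field(), 1.0)
    sat = np.clip(tex.saturation + 0.08 * _field(), 0.15, 1.0)
    val = np.clip(0.72 + 0.10 * _field(), 0.45, 0.95)
    rgb = hsv2rgb(np.stack([hue, sat, val], axis=-1))
    return (rgb * 255.0 + 0.5).astype(np.uint8)


def _rasterize(poly: Polygon, height: int, width: int, origin=(0, 0)) -> np.ndarray:
    """Boolean mask of the polygon interior over a local window."""
    ox, oy = origin
    img = Image.new("1", (width, height), 0)
    pts = [(x - ox, y - oy) for x, y in np.asarray(poly.exterior.coords)]
    ImageDraw.Draw(img).polygon(pts, fill=1)
    return np.asarray(img, dtype=bool)


def _paint_polygon(
    canvas: np.ndarray, poly: Polygon, tex: TextureParams, rng: np.random.Generator
) -> None:
    minx, miny, maxx, maxy = poly.bounds
    x0, y0 = max(0, int(minx) - 1), max(0, int(miny) - 1)
    x1 = min(canvas.shape[1], int(np.ceil(maxx)) + 2)
    y1 = min(canvas.shape[0], int(np.ceil(maxy)) + 2)
    mask = _rasterize(poly, y1 - y0, x1 - x0, origin=(x0, y0))
    patch = _texture_rgb(rng, y1 - y0, x1 - x0, tex)
    window = canvas[y0:y1, x0:x1]
    window[mask] = patch[mask]


def _place_regions(
    spec: SyntheticSpec, rng: np.random.Generator, slide_id: str
) -> list:
    """Non-overlapping labelled blobs; bounded rejection sampling."""
    placed = []  # (polygon, label)
    w, h = spec.slide_width_px, spec.slide_height_px
    lo, hi = spec.region_radius_px
    for label in LABELS:  # priority order keeps placement deterministic
        for _ in range(spec.n_regions_per_label.get(label, 0)):
            for _attempt in range(200):
                radius = rng.uniform(lo, hi)
                margin = radius * 1.15 + 4
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
                poly = _blob_polygon(rng, cx, cy, radius)
                if all(poly.distance(p) > 32 for p, _ in placed):
                    placed.append((poly, label))
                    break
            else:
                raise PlacementError(
                    f"could not place a {label} region of radius in "
                    f"{spec.region_radius_px} on slide {slide_id!r} "
                    f"({w}x{h}, {sum(spec.n_regions_per_label.values())} regions requested)"
                )
    return placed


def _place_speck(
    spec: SyntheticSpec, rng: np.random.Generator, regions: list
) -> Polygon | None:
    """A small off-label disc on the background, clear of every region."""
    r = spec.speck_diameter_px / 2.0
    w, h = spec.slide_width_px, spec.slide_height_px
    for _ in range(500):
        cx = rng.uniform(r + 32, w - r - 32)
        cy = rng.uniform(r + 32, h - r - 32)
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        disc = Polygon(
            np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        )
        if all(disc.distance(p) > spec.speck_clearance_px for p, _ in regions):
            return disc
    log.warning("no room for a false-positive speck; slide generated without one")
    return None


def _speck_label(region_labels: set) -> str | None:
    """Highest-priority label absent from the slide's own annotations."""
    for label in LABELS:
        if label not in region_labels:
            return label
    return None


def write_annotations(record: SlideRecord, path: Path) -> None:
    """GeoJSON FeatureCollection; speck features carry ``"speck": true``."""
    features = []
    for polys, is_speck in ((record.regions, False), (record.specks, True)):
        for poly, label in polys:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {"label": label, "speck": is_speck},
                }
            )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_annotations(path: Path) -> tuple[list, list]:
    """Inverse of :func:`write_annotations` -> (regions, specks)."""
    payload = json.loads(Path(path).read_text())
    regions, specks = [], []
    for feat in payload["features"]:
        poly = shape(feat["geometry"])
        label = check_label(feat["properties"]["label"])
        target = specks if feat["properties"].get("speck") else regions
        target.append((poly, label))
    return regions, specks


def generate_slide(spec: SyntheticSpec, slide_id: str, out_dir: Path) -> SlideRecord:
    """Write one synthetic slide (TIFF + GeoJSON) and return its record.

    Raises :class:`PlacementError` when the requested regions cannot be
    placed without overlap, and OSError when ``out_dir`` is unwritable.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _slide_rng(spec, slide_id)

    regions = _place_regions(spec, rng, slide_id)
    canvas = np.full(
        (spec.slide_height_px, spec.slide_width_px, 3), 255, dtype=np.uint8
    )
    for poly, label in regions:
        _paint_polygon(canvas, poly, spec.texture_params[label], rng)

    specks = []
    # consume one uniform draw unconditionally so the layout of the rest of
    # the slide does not depend on the speck-rate setting
    speck_draw = rng.uniform()
    if regions and speck_draw < spec.false_positive_speck_rate:
        label = _speck_label({lab for _, lab in regions})
        if label is not None:
            disc = _place_speck(spec, rng, regions)
            if disc is not None:
                _paint_polygon(canvas, disc, spec.texture_params[label], rng)
                specks.append((disc, label))

    image_path = out_dir / f"{slide_id}.tiff"
    tifffile.imwrite(image_path, canvas, photometric="rgb")

    region_labels = {label for _, label in regions}
    record = SlideRecord(
        slide_id=slide_id,
        image_uri=image_path,
        width_px=spec.slide_width_px,
        height_px=spec.slide_height_px,
        regions=regions,
        specks=specks,
        slide_label=_priority_label(region_labels) if region_labels else None,
    )
    write_annotations(record, record.annotation_uri)
    return record


def _priority_label(labels: set) -> str:
    for label in LABELS:
        if label in labels:
            return label
    raise ValueError(f"no known label in {labels}")


def _composition_for(spec: SyntheticSpec, slide_label: str) -> dict:
    """Region counts for a slide of a given intended diagnosis.

    A slide carries regions of its own label plus non-neoplastic tissue
    (benign background tissue is present on every real biopsy); it never
    carries regions of a *higher*-priority label, which would contradict
    the slide-level diagnosis under the priority rule.
    """
    n = spec.n_regions_per_label
    if slide_label == NON_NEOPLASTIC:
        return {NON_NEOPLASTIC: max(1, n.get(NON_NEOPLASTIC, 1)) + 1}
    return {
        slide_label: max(1, n.get(slide_label, 1)),
        NON_NEOPLASTIC: max(1, n.get(NON_NEOPLASTIC, 1)),
    }


def generate_cohort(
    spec: SyntheticSpec,
    n_train_per_label: dict,
    n_test_per_label: dict | None,
    out_dir: Path,
) -> tuple[list, Path]:
    """Generate a train/test cohort and its manifest CSV.

    Returns (records, manifest_path). The manifest has columns
    ``slide_id,path,slide_label,split``; the GeoJSON annotation for each
    slide sits next to its TIFF with the same stem.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_test_per_label = n_test_per_label or {}
    records, rows = [], []
    for split, counts in (("train", n_train_per_label), ("test", n_test_per_label)):
        for label in LABELS:
            count = counts.get(label, 0)
            if count < 0:
                raise ValueError(f"negative slide count for {label}")
            for i in range(count):
                slide_id = f"{label}_{split}_{i:03d}"
                slide_spec = replace(
                    spec, n_regions_per_label=_composition_for(spec, label)
                )
                record = generate_slide(slide_spec, slide_id, out_dir)
                if record.slide_label != label:
                    raise AssertionError(
                        f"slide {slide_id} composition yields label "
                        f"{record.slide_label}, wanted {label}"
                    )
                records.append(record)
                rows.append((slide_id, str(record.image_uri), label, split))
    manifest = out_dir / "cohort.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "path", "slide_label", "split"])
        writer.writerows(rows)
    return records, manifest


def read_cohort(manifest: Path) -> list:
    """Load SlideRecords from a cohort manifest CSV."""
    records = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            image = Path(row["path"])
            with tifffile.TiffFile(image) as tif:
                page = tif.pages[0]
                height, width = page.shape[:2]
            record = SlideRecord(
                slide_id=row["slide_id"],
                image_uri=image,
                width_px=width,
                height_px=height,
                slide_label=row["slide_label"] or None,
            )
            ann = record.annotation_uri
            if ann.exists():
                record.regions, record.specks = load_annotations(ann)
            record.split = row.get("split", "")
            records.append(record)
    return records
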