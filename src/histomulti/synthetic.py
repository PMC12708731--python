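"""Synthetic co-registered 10x/40x H&E-like patch generator.

Real multiscale histopathology pipelines consume paired patches cut from
whole-slide images at two objective powers, plus nuclei centroids and tumor
masks.  This module fabricates all of those from scratch, deterministically:
a high-resolution canvas is rendered (eosin-pink textured background, filled
elliptical hematoxylin-purple nuclei, optionally a denser and more
pleomorphic "tumor" blob), then the 40x patch is the central crop at native
resolution and the 10x patch is the 4x block-downsampled full canvas.  The
two views therefore share a field of view by construction: the 40x patch
magnifies the central quarter-side region of the 10x patch.

Coordinates are 0-based, origin top-left, x = column, y = row; centroid
tables live in the 40x frame.  Masks are written as 8-bit PNGs with
255 = tumor.  The generator is bit-reproducible in (seed, pair_id).
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "SyntheticSlideSpec",
    "NucleusRecord",
    "MultiResPatchPair",
    "DatasetManifest",
    "generate_patch_pair",
    "generate_dataset",
    "generate_superpixels",
    "load_manifest",
    "load_pair",
]

MAG_RATIO = 4  # 10x -> 40x is a 4x linear magnification step


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Conditions under which synthetic slides are rendered.

    ``canvas_px`` is the side of the high-resolution render; emitted patches
    are ``canvas_px // 4`` square.  ``n_nuclei_normal`` nuclei are scattered
    over the whole canvas outside any tumor blob; ``n_nuclei_tumor`` extra
    nuclei are packed inside the blob, giving the density contrast real
    tumor regions show.  ``pleomorphism`` scales the radius/eccentricity
    variability of tumor nuclei.
    """

    seed: int = 0
    canvas_px: int = 512
    n_nuclei_normal: int = 150
    n_nuclei_tumor: int = 200
    tumor_fraction: float = 0.5
    nucleus_radius_px: tuple = (6.0, 1.0)
    pleomorphism: float = 1.5
    stain_palette: tuple = ((232, 180, 200), (92, 64, 140))  # (eosin bg, hematoxylin nuclei)
    noise_sd: float = 6.0

    def __post_init__(self):
        if self.canvas_px <= 0:
            raise ValueError("canvas_px must be positive")
        if self.canvas_px % 32:
            raise ValueError("canvas_px must be divisible by 32")
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.n_nuclei_normal < 0 or self.n_nuclei_tumor < 0:
            raise ValueError("nucleus counts must be >= 0")
        if self.noise_sd < 0 or self.pleomorphism < 0:
            raise ValueError("noise_sd and pleomorphism must be >= 0")


@dataclass(frozen=True)
class NucleusRecord:
    x: float  # column, 40x-frame pixels
    y: float  # row, 40x-frame pixels
    radius: float
    cls: str  # {"tumor", "normal"}


@dataclass
class MultiResPatchPair:
    pair_id: int
    image10: np.ndarray  # (H, W, 3) uint8
    image40: np.ndarray  # (H, W, 3) uint8
    mask10: np.ndarray  # (H, W) bool
    mask40: np.ndarray  # (H, W) bool
    centroids: list  # NucleusRecord, 40x frame
    label: str  # {"tumor", "normal"}
    crop_offset: tuple  # (row, col) of the 40x field of view, in 10x pixels


@dataclass
class DatasetManifest:
    records: list
    spec: SyntheticSlideSpec
    root: Path | None = None


def _pair_rng(spec: SyntheticSlideSpec, pair_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(pair_id)]))


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    h, w = img.shape[:2]
    out = img.reshape(h // f, f, w // f, f, -1).mean(axis=(1, 3))
    return out


def _draw_nucleus(canvas, rng, cy, cx, radius, ecc_sd, color, darken):
    ecc = abs(rng.normal(0.0, ecc_sd))
    a = max(1.0, radius * (1.0 + ecc))
    b = max(1.0, radius / (1.0 + ecc))
    rot = rng.uniform(0.0, math.pi)
    jitter = rng.normal(0.0, 10.0, 3)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=canvas.shape[:2], rotation=rot)
    canvas[rr, cc] = np.clip(np.asarray(color, float) + jitter - darken, 0, 255)


def generate_patch_pair(spec: SyntheticSlideSpec, pair_id: int) -> MultiResPatchPair:
    """Render one co-registered 10x/40x pair, deterministic in (spec.seed, pair_id)."""
    rng = _pair_rng(spec, pair_id)
    c = spec.canvas_px
    patch = c // MAG_RATIO
    crop0 = (c - patch) // 2  # canvas-frame origin of the 40x field of view

    # background: eosin palette + smooth low-frequency texture
    low = gaussian_filter(rng.normal(0.0, 1.0, (c, c)), sigma=c / 32.0)
    sd = low.std()
    low = low / sd * 18.0 if sd > 0 else low
    canvas = np.empty((c, c, 3))
    for ch, scale in enumerate((1.0, 0.85, 0.95)):
        canvas[:, :, ch] = spec.stain_palette[0][ch] + low * scale

    # tumor blob (decided before any nucleus placement so the RNG stream is stable)
    is_tumor = rng.random() < spec.tumor_fraction
    mask = np.zeros((c, c), dtype=bool)
    if is_tumor:
        margin = patch // 8
        cy = rng.uniform(crop0 + margin, crop0 + patch - margin)
        cx = rng.uniform(crop0 + margin, crop0 + patch - margin)
        a = rng.uniform(c / 8.0, c / 4.0)
        b = rng.uniform(c / 8.0, c / 4.0)
        rot = rng.uniform(0.0, math.pi)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(c, c), rotation=rot)
        mask[rr, cc] = True

    r_mean, r_sd = spec.nucleus_radius_px
    nuclei: list[tuple[float, float, float, str]] = []

    # normal nuclei scattered outside the blob
    placed = 0
    while placed < spec.n_nuclei_normal:
        y, x = rng.uniform(0, c), rng.uniform(0, c)
        if mask[int(y), int(x)]:
            continue
        radius = max(1.5, rng.normal(r_mean, r_sd))
        _draw_nucleus(canvas, rng, y, x, radius, 0.1, spec.stain_palette[1], 0.0)
        nuclei.append((x, y, radius, "normal"))
        placed += 1

    # tumor nuclei packed inside the blob: denser, larger, more pleomorphic
    if is_tumor:
        placed = 0
        while placed < spec.n_nuclei_tumor:
            y, x = rng.uniform(0, c), rng.uniform(0, c)
            if not mask[int(y), int(x)]:
                continue
            radius = max(1.5, rng.normal(r_mean * 1.3, r_sd * (1.0 + spec.pleomorphism)))
            _draw_nucleus(
                canvas, rng, y, x, radius,
                0.1 * (1.0 + spec.pleomorphism), spec.stain_palette[1], 18.0,
            )
            nuclei.append((x, y, radius, "tumor"))
            placed += 1

    canvas += rng.normal(0.0, spec.noise_sd, canvas.shape)
    canvas = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    image40 = canvas[crop0 : crop0 + patch, crop0 : crop0 + patch].copy()
    image10 = np.clip(np.round(_block_mean(canvas, MAG_RATIO)), 0, 255).astype(np.uint8)
    mask40 = mask[crop0 : crop0 + patch, crop0 : crop0 + patch].copy()
    mask10 = mask.reshape(patch, MAG_RATIO, patch, MAG_RATIO).any(axis=(1, 3))

    centroids = [
        NucleusRecord(x - crop0, y - crop0, r, cls)
        for (x, y, r, cls) in nuclei
        if crop0 <= x < crop0 + patch and crop0 <= y < crop0 + patch
    ]
    label = "tumor" if mask40.any() else "normal"
    return MultiResPatchPair(
        pair_id=pair_id,
        image10=image10,
        image40=image40,
        mask10=mask10,
        mask40=mask40,
        centroids=centroids,
        label=label,
        crop_offset=(crop0 // MAG_RATIO, crop0 // MAG_RATIO),
    )


def _write_png(path: Path, arr: np.ndarray):
    Image.fromarray(arr).save(path)


def generate_dataset(spec: SyntheticSlideSpec, n_pairs: int, out_dir) -> DatasetManifest:
    """Write `n_pairs` pairs to `out_dir`: PNGs, centroid CSVs, and a JSON manifest."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for pid in range(n_pairs):
        pair = generate_patch_pair(spec, pid)
        stem = f"pair_{pid:04d}"
        files = {
            "image10": f"{stem}_10x.png",
            "image40": f"{stem}_40x.png",
            "mask10": f"{stem}_mask10.png",
            "mask40": f"{stem}_mask40.png",
            "centroids": f"{stem}_centroids.csv",
        }
        _write_png(out / files["image10"], pair.image10)
        _write_png(out / files["image40"], pair.image40)
        _write_png(out / files["mask10"], pair.mask10.astype(np.uint8) * 255)
        _write_png(out / files["mask40"], pair.mask40.astype(np.uint8) * 255)
        with open(out / files["centroids"], "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", "radius", "cls"])
            for n in pair.centroids:
                w.writerow([f"{n.x:.3f}", f"{n.y:.3f}", f"{n.radius:.3f}", n.cls])
        records.append(
            {"pair_id": pid, **files, "label": pair.label, "seed": int(spec.seed),
             "crop_offset": list(pair.crop_offset)}
        )
    manifest = DatasetManifest(records=records, spec=spec, root=out)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"spec": asdict(spec), "records": records}, fh, indent=1)
    return manifest


def load_manifest(path) -> DatasetManifest:
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    spec_d = raw["spec"]
    spec_d["nucleus_radius_px"] = tuple(spec_d["nucleus_radius_px"])
    spec_d["stain_palette"] = tuple(tuple(c) for c in spec_d["stain_palette"])
    return DatasetManifest(records=raw["records"], spec=SyntheticSlideSpec(**spec_d),
                           root=path.parent)


def load_pair(manifest: DatasetManifest, record: dict) -> MultiResPatchPair:
    root = manifest.root
    img = lambda k: np.asarray(Image.open(root / record[k]))
    centroids = []
    with open(root / record["centroids"]) as fh:
        for row in csv.DictReader(fh):
            centroids.append(NucleusRecord(float(row["x"]), float(row["y"]),
                                           float(row["radius"]), row["cls"]))
    return MultiResPatchPair(
        pair_id=record["pair_id"],
        image10=img("image10"),
        image40=img("image40"),
        mask10=img("mask10") > 127,
        mask40=img("mask40") > 127,
        centroids=centroids,
        label=record["label"],
        crop_offset=tuple(record["crop_offset"]),
    )


def generate_superpixels(image: np.ndarray, n_segments: int, method: str = "slic") -> np.ndarray:
    """Segment an RGB image into superpixels; labels contiguous from 0.

    ``slic`` uses the standard k-means-in-color-space algorithm; ``grid``
    tiles the image into ceil(sqrt(n_segments))^2 rectangles and serves as a
    dependency-free fallback and a fully predictable test fixture.
    """
    h, w = image.shape[:2]
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > h * w:
        raise ValueError("n_segments exceeds pixel count")
    if method == "grid":
        g = math.isqrt(n_segments)
        if g * g < n_segments:
            g += 1
        rows = np.minimum(np.arange(h) * g // h, g - 1)
        cols = np.minimum(np.arange(w) * g // w, g - 1)
        return (rows[:, None] * g + cols[None, :]).astype(np.int64)
    if method == "slic":
        from skimage.segmentation import slic

        labels = slic(image, n_segments=n_segments, start_label=0, channel_axis=-1)
        _, relabeled = np.unique(labels, return_inverse=True)
        return relabeled.reshape(labels.shape).astype(np.int64)
    raise ValueError(f"unknown superpixel method: {method!r}")


def file_digest(path) -> str:
    """SHA-256 of a file, for reproducibility checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
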