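"""Synthetic mosquito-swarm images with exact point labels.

The generator emulates the statistical structure of field-collected swarm
photographs — small dark elongated blobs on a lighter, lightly textured
background, per-image counts spanning empty to dense, eight per-image size
classes, and occasional touching/overlapping blobs ("adhesion") — without
claiming visual fidelity (no wings, legs, motion blur or perspective).  Each
blob is an anti-aliased filled ellipse (axis ratio about 3:1, random
orientation) whose length scales with the size class's Gaussian width, and
its annotation is exactly the integer centre pixel used to place it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations_io import (AnnotatedImage, DatasetManifest, ManifestEntry,
                             N_SIZE_CLASSES, PointAnnotation, save_image,
                             save_manifest, write_annotations)
from .density import assign_sigma

__all__ = ["SynthConfig", "render_swarm", "blob_half_length", "make_dataset",
           "sample_images"]


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic swarm image."""

    image_size: tuple[int, int] = (540, 960)  # (H, W), the dataset's frame
    count_range: tuple[int, int] = (0, 150)  # sparse to dense swarms
    size_class: int = 4
    adhesion_prob: float = 0.2  # chance a blob is placed touching another
    background_mean: float = 170.0  # light grey backdrop
    background_noise: float = 8.0  # sensor-noise std (intensity units)
    background_gradient: float = 20.0  # low-frequency illumination ramp
    blob_axis_ratio: float = 3.0  # length : width of the ellipse
    blob_intensity: tuple[float, float] = (30.0, 90.0)  # darker than backdrop
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.size_class <= N_SIZE_CLASSES:
            raise ValueError(f"size_class must be in 1..8, got {self.size_class}")
        lo, hi = self.count_range
        if lo < 0 or hi < lo:
            raise ValueError(f"bad count_range {self.count_range}")
        if not 0.0 <= self.adhesion_prob <= 1.0:
            raise ValueError("adhesion_prob must be in [0, 1]")


def blob_half_length(size_class: int) -> float:
    """Characteristic semi-major axis (pixels) of a blob of this class;
    proportional to the class's density-map sigma so blob scale and kernel
    width stay consistent."""
    return 1.5 * assign_sigma(size_class)


def _soft_ellipse(patch_shape: tuple[int, int], centre: tuple[float, float],
                  a: float, b: float, angle: float) -> np.ndarray:
    """Anti-aliased coverage mask in [0, 1] of a rotated filled ellipse."""
    rr, cc = np.mgrid[0:patch_shape[0], 0:patch_shape[1]]
    dy, dx = rr - centre[0], cc - centre[1]
    ca, sa = math.cos(angle), math.sin(angle)
    xr = ca * dx + sa * dy
    yr = -sa * dx + ca * dy
    q = (xr / a) ** 2 + (yr / b) ** 2
    # ~1 inside, 0 outside, linear roll-off across the rim
    return np.clip((1.0 - q) * 2.5, 0.0, 1.0)


def render_swarm(config: SynthConfig) -> AnnotatedImage:
    """Render one swarm image; reproducible bitwise from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    a = blob_half_length(config.size_class)
    b = max(a / config.blob_axis_ratio, 0.8)
    lo, hi = config.count_range
    count = int(rng.integers(lo, hi + 1))
    if count * math.pi * a * b > 0.5 * h * w:
        raise ValueError(
            f"count range {config.count_range} infeasible for a {h}x{w} "
            f"image with class-{config.size_class} blobs")

    # background: grey + random-direction illumination ramp
    canvas = np.full((h, w), config.background_mean, dtype=np.float64)
    if config.background_gradient > 0:
        theta = rng.uniform(0, 2 * math.pi)
        rr, cc = np.mgrid[0:h, 0:w]
        ramp = (math.cos(theta) * rr / max(h - 1, 1)
                + math.sin(theta) * cc / max(w - 1, 1))
        canvas += config.background_gradient * (ramp - ramp.mean())

    margin = int(math.ceil(a)) + 1
    centres: list[tuple[int, int]] = []
    for _ in range(count):
        adhere = centres and rng.random() < config.adhesion_prob
        if adhere:
            ar, ac = centres[int(rng.integers(len(centres)))]
            radius = rng.uniform(0.5, 1.5) * 2 * a  # within 1.5 blob-lengths
            phi = rng.uniform(0, 2 * math.pi)
            r = int(round(ar + radius * math.sin(phi)))
            c = int(round(ac + radius * math.cos(phi)))
            r = min(max(r, margin), h - 1 - margin)
            c = min(max(c, margin), w - 1 - margin)
        else:
            r = int(rng.integers(margin, h - margin))
            c = int(rng.integers(margin, w - margin))
        centres.append((r, c))
        angle = rng.uniform(0, math.pi)
        intensity = rng.uniform(*config.blob_intensity)
        rad = int(math.ceil(a)) + 1
        r0, r1 = r - rad, r + rad + 1
        c0, c1 = c - rad, c + rad + 1
        alpha = _soft_ellipse((r1 - r0, c1 - c0), (r - r0, c - c0), a, b, angle)
        region = canvas[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1] = region * (1 - alpha) + intensity * alpha

    if config.background_noise > 0:
        canvas += rng.normal(0.0, config.background_noise, size=canvas.shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)
    points = [PointAnnotation(r, c) for r, c in centres]
    return AnnotatedImage(image=image, points=points,
                          size_class=config.size_class,
                          image_id=f"synth-{config.seed}")


def _class_probs(class_mix) -> np.ndarray:
    if class_mix is None or (isinstance(class_mix, str) and class_mix == "uniform"):
        p = np.ones(N_SIZE_CLASSES)
    elif isinstance(class_mix, dict):
        p = np.array([float(class_mix.get(c, 0.0))
                      for c in range(1, N_SIZE_CLASSES + 1)])
    else:
        p = np.asarray(list(class_mix), dtype=np.float64)
        if p.size != N_SIZE_CLASSES:
            raise ValueError(f"class_mix needs {N_SIZE_CLASSES} weights")
    if p.sum() <= 0 or (p < 0).any():
        raise ValueError("class_mix weights must be non-negative, not all zero")
    return p / p.sum()


def make_dataset(out_dir: str | Path, n_train: int, n_test: int,
                 class_mix="uniform", seed: int = 0,
                 base_config: SynthConfig | None = None) -> DatasetManifest:
    """Write a synthetic dataset (PNG images, CSV annotations, manifest).

    Size classes are drawn from ``class_mix`` (uniform by default, or eight
    weights / a {class: weight} dict).  Everything derives from ``seed``.
    Returns the manifest, also written to ``out_dir/manifest.csv``.
    """
    if n_train < 0 or n_test < 0:
        raise ValueError("n_train and n_test must be >= 0")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    base = base_config if base_config is not None else SynthConfig()
    probs = _class_probs(class_mix)
    rng = np.random.default_rng(seed)

    entries: list[ManifestEntry] = []
    splits = ["train"] * n_train + ["test"] * n_test
    for i, split in enumerate(splits):
        size_class = int(rng.choice(np.arange(1, N_SIZE_CLASSES + 1), p=probs))
        img_seed = int(rng.integers(0, 2 ** 31 - 1))
        cfg = replace(base, size_class=size_class, seed=img_seed)
        annotated = render_swarm(cfg)
        image_id = f"{split}_{i:04d}"
        img_path = out_dir / "images" / f"{image_id}.png"
        ann_path = out_dir / "annotations" / f"{image_id}.csv"
        save_image(annotated.image, img_path)
        write_annotations(annotated, ann_path)
        entries.append(ManifestEntry(image=img_path, annotations=ann_path,
                                     size_class=size_class, split=split))
    manifest = DatasetManifest(entries=entries)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def sample_images(n: int, seed: int = 0, class_mix="uniform",
                  base_config: SynthConfig | None = None
                  ) -> list[AnnotatedImage]:
    """In-memory batch of synthetic images (no files written)."""
    base = base_config if base_config is not None else SynthConfig()
    probs = _class_probs(class_mix)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        size_class = int(rng.choice(np.arange(1, N_SIZE_CLASSES + 1), p=probs))
        img_seed = int(rng.integers(0, 2 ** 31 - 1))
        img = render_swarm(replace(base, size_class=size_class, seed=img_seed))
        img.image_id = f"mem_{i:04d}"
        out.append(img)
    return out
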