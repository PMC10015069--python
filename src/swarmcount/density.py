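"""Ground-truth density maps from point annotations.

A density map is a non-negative 2-D field whose integral equals the object
count: each annotated point contributes a unit-mass isotropic Gaussian whose
width sigma is set by the image's size class.  Eight empirical size classes
map monotonically onto sigma in {2..9} pixels.  Because the network predicts
on a coarser grid (1/8 of the input for the default front end), maps are
generated at full resolution and sum-pooled, which conserves mass exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations_io import N_SIZE_CLASSES, PointAnnotation

__all__ = [
    "DensityMap",
    "SIGMA_OF_CLASS",
    "assign_sigma",
    "gaussian_kernel",
    "generate_density_map",
    "density_map_for",
    "downsample_mass_preserving",
    "save_density_map",
    "load_density_map",
]

#: Size class (1..8) -> Gaussian standard deviation in pixels.  The class
#: index increases with apparent mosquito size, so sigma = class + 1 spans
#: exactly {2..9}.  Replaceable by any monotone mapping onto {2..9}.
SIGMA_OF_CLASS: dict[int, float] = {c: float(c + 1) for c in range(1, N_SIZE_CLASSES + 1)}


@dataclass
class DensityMap:
    """2-D density field; ``scale`` is the downsampling factor vs the source
    image (1 = full resolution).  Values are mosquitoes per pixel."""

    values: np.ndarray
    scale: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"density map must be 2-D, got {self.values.ndim}-D")
        if self.scale < 1:
            raise ValueError(f"scale must be >= 1, got {self.scale}")

    @property
    def mass(self) -> float:
        """Total integral of the map = (possibly fractional) object count."""
        return float(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def assign_sigma(size_class: int) -> float:
    """Gaussian width (pixels) for a size class in 1..8."""
    if size_class not in SIGMA_OF_CLASS:
        raise ValueError(f"size_class must be in 1..{N_SIZE_CLASSES}, got {size_class}")
    return SIGMA_OF_CLASS[size_class]


def gaussian_kernel(sigma: float, truncation: float = 4.0) -> np.ndarray:
    """Square isotropic Gaussian kernel, normalized to unit sum.

    Side length is ``2*ceil(truncation*sigma) + 1`` so the kernel covers
    +-truncation standard deviations around the centre pixel.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if truncation <= 0:
        raise ValueError(f"truncation must be positive, got {truncation}")
    radius = int(math.ceil(truncation * sigma))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def generate_density_map(points: Sequence[PointAnnotation],
                         shape: tuple[int, int],
                         sigma: float,
                         renormalize_boundary: bool = True,
                         truncation: float = 4.0) -> DensityMap:
    """Sum of unit-mass Gaussians centred on the annotated points.

    Each point stamps a truncated Gaussian kernel; near the border the
    kernel is clipped by the image edge, and with ``renormalize_boundary``
    on the clipped patch is rescaled so every point still contributes total
    mass exactly 1 (count-by-integration then recovers ``len(points)``).
    With the flag off, clipped mass is simply lost (total <= N).
    """
    h, w = shape
    values = np.zeros((h, w), dtype=np.float64)
    if not points:
        return DensityMap(values, scale=1)
    kernel = gaussian_kernel(sigma, truncation)
    radius = kernel.shape[0] // 2
    for i, p in enumerate(points):
        r, c = p.row, p.col
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"point {i} = ({r}, {c}) outside {h}x{w} map")
        r0, r1 = max(r - radius, 0), min(r + radius + 1, h)
        c0, c1 = max(c - radius, 0), min(c + radius + 1, w)
        patch = kernel[r0 - r + radius:r1 - r + radius,
                       c0 - c + radius:c1 - c + radius]
        if renormalize_boundary:
            patch = patch / patch.sum()
        values[r0:r1, c0:c1] += patch
    return DensityMap(values, scale=1)


def density_map_for(annotated, renormalize_boundary: bool = True,
                    truncation: float = 4.0) -> DensityMap:
    """Ground-truth map for an AnnotatedImage, using its size class's sigma."""
    return generate_density_map(
        annotated.points, annotated.shape, assign_sigma(annotated.size_class),
        renormalize_boundary=renormalize_boundary, truncation=truncation)


def downsample_mass_preserving(dmap: DensityMap, factor: int) -> DensityMap:
    """Sum-pool by ``factor``: each output cell is the sum of its
    factor x factor input block (partial edge blocks summed as-is), so the
    total mass is conserved exactly.  Output shape is ceil(H/f) x ceil(W/f).
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return DensityMap(dmap.values.copy(), scale=dmap.scale)
    h, w = dmap.shape
    oh, ow = -(-h // factor), -(-w // factor)
    padded = np.zeros((oh * factor, ow * factor), dtype=np.float64)
    padded[:h, :w] = dmap.values
    pooled = padded.reshape(oh, factor, ow, factor).sum(axis=(1, 3))
    return DensityMap(pooled, scale=dmap.scale * factor)


def save_density_map(dmap: DensityMap, path: str | Path,
                     image_id: str = "") -> Path:
    """Serialize as ``.npy`` plus a JSON sidecar with id, scale and mass."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), dmap.values)
    sidecar = {"image_id": image_id, "scale": dmap.scale, "mass": dmap.mass}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def load_density_map(path: str | Path) -> tuple[DensityMap, dict]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return DensityMap(values, scale=int(meta.get("scale", 1))), meta
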