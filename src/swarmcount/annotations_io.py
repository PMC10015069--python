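"""Image + point-annotation I/O and dataset manifest handling.

Conventions shared by every other module:

* Coordinates are 0-based integer pixel indices, ``(row, col)`` with *row*
  vertical.  Annotation files are per-image CSVs with header ``row,col``.
* Each image carries one *size class* in 1..8 describing the apparent
  mosquito size; the class lives in the dataset manifest, not in the
  annotation file, because it is a per-image property.
* The manifest is a CSV with columns ``image,annotations,size_class,split``;
  paths are resolved relative to the manifest's own directory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PointAnnotation",
    "AnnotatedImage",
    "ManifestEntry",
    "DatasetManifest",
    "read_points",
    "write_annotations",
    "read_annotated_image",
    "load_image",
    "save_image",
    "load_manifest",
    "save_manifest",
]

N_SIZE_CLASSES = 8


@dataclass(frozen=True)
class PointAnnotation:
    """A single labelled mosquito location (0-based pixel indices)."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError(f"negative coordinates: ({self.row}, {self.col})")


@dataclass
class AnnotatedImage:
    """An RGB image with its point annotations and per-image size class.

    The ground-truth count ``N`` of the image is defined as
    ``len(self.points)`` and nothing else.
    """

    image: np.ndarray  # H x W x 3, uint8
    points: list[PointAnnotation]
    size_class: int
    image_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim == 2:  # grayscale -> replicate to 3 channels
            self.image = np.repeat(self.image[:, :, None], 3, axis=2)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"expected HxWx3 image, got shape {self.image.shape}")
        if not 1 <= self.size_class <= N_SIZE_CLASSES:
            raise ValueError(
                f"size_class must be in 1..{N_SIZE_CLASSES}, got {self.size_class}"
            )
        h, w = self.image.shape[:2]
        for i, p in enumerate(self.points):
            if not (0 <= p.row < h and 0 <= p.col < w):
                raise ValueError(
                    f"point {i} = (row={p.row}, col={p.col}) outside "
                    f"{h}x{w} image bounds"
                )

    @property
    def count(self) -> int:
        """Ground-truth object count: the number of annotated points."""
        return len(self.points)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[0], self.image.shape[1]


@dataclass(frozen=True)
class ManifestEntry:
    image: Path
    annotations: Path
    size_class: int
    split: str  # "train" | "test"

    @property
    def image_id(self) -> str:
        return self.image.stem


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def split(self, which: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == which]

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        """Check path resolution and image-id uniqueness per split."""
        for e in self.entries:
            for p in (e.image, e.annotations):
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
            if not 1 <= e.size_class <= N_SIZE_CLASSES:
                raise ValueError(f"{e.image}: size_class {e.size_class} not in 1..8")
        for which in ("train", "test"):
            ids = [e.image_id for e in self.split(which)]
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ValueError(f"duplicate image ids in split {which!r}: {dupes}")


def read_points(path: str | Path) -> list[PointAnnotation]:
    """Read a ``row,col`` CSV into a list of points (may be empty)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:2]] != ["row", "col"]:
            raise ValueError(f"{path}: expected header 'row,col', got {header}")
        points = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            try:
                points.append(PointAnnotation(int(rec[0]), int(rec[1])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed point {rec}") from exc
    return points


def write_annotations(annotated: AnnotatedImage | Sequence[PointAnnotation],
                      path: str | Path) -> Path:
    """Write point annotations as a ``row,col`` CSV.

    Round-trip contract: ``read_points(write_annotations(a, p))`` reproduces
    the points exactly (integer coordinates, order preserved).
    """
    points: Iterable[PointAnnotation]
    points = annotated.points if isinstance(annotated, AnnotatedImage) else annotated
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col"])
        for p in points:
            writer.writerow([p.row, p.col])
    return path


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an H x W x 3 uint8 array (grayscale replicated)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)
    return path


def read_annotated_image(image_path: str | Path,
                         annotation_path: str | Path,
                         size_class: int,
                         image_id: str | None = None) -> AnnotatedImage:
    """Load one image with its annotations, validating points against bounds."""
    image = load_image(image_path)
    points = read_points(annotation_path)
    if image_id is None:
        image_id = Path(image_path).stem
    return AnnotatedImage(image=image, points=points, size_class=size_class,
                          image_id=image_id)


def load_annotated(entry: ManifestEntry) -> AnnotatedImage:
    return read_annotated_image(entry.image, entry.annotations, entry.size_class)


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest CSV; relative paths resolve against the CSV's folder."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"image", "annotations", "size_class", "split"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    base = path.parent
    entries = [
        ManifestEntry(
            image=base / str(r.image),
            annotations=base / str(r.annotations),
            size_class=int(r.size_class),
            split=str(r.split),
        )
        for r in df.itertuples()
    ]
    return DatasetManifest(entries=entries)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Write the manifest CSV with paths relative to its directory."""
    path = Path(path)
    base = path.parent

    def rel(p: Path) -> str:
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    df = pd.DataFrame(
        {
            "image": [rel(e.image) for e in manifest.entries],
            "annotations": [rel(e.annotations) for e in manifest.entries],
            "size_class": [e.size_class for e in manifest.entries],
            "split": [e.split for e in manifest.entries],
        }
    )
    df.to_csv(path, index=False)
    return path
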