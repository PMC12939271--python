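"""Label-map and grayscale raster I/O, the FDI class schema, and preprocessing.

A panoramic tooth segmentation is represented as a 33-class label map: pixel
value 0 is background and values 1..32 map bijectively onto the 32 permanent
teeth of the FDI two-digit numbering system.  The preprocessing stage brings
any raster to the pipeline's working geometry of 512 rows x 1024 columns.

Raster convention: 0-based, row-major, origin at the top-left; the row index
increases downward.  The image's upper border is row 0 (maxillary reference),
the lower border is the last row (mandibular reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

#: Working raster geometry (rows, cols) every image is resampled to.
TARGET_SHAPE: tuple[int, int] = (512, 1024)

#: Number of classes in a label map: 32 FDI teeth plus background.
N_CLASSES: int = 33

_TOOTH_TYPES = (
    "central incisor",
    "lateral incisor",
    "canine",
    "first premolar",
    "second premolar",
    "first molar",
    "second molar",
    "third molar",
)

# Canonical class-index <-> FDI table, shipped as plain text so it can be
# inspected or replaced.  class = 8*(quadrant-1) + position.
DEFAULT_SCHEMA_TABLE = "\n".join(
    f"{8 * (q - 1) + p}\t{10 * q + p}" for q in (1, 2, 3, 4) for p in range(1, 9)
)


@dataclass(frozen=True)
class FDIEntry:
    class_index: int
    fdi_code: str
    arch: str        # "maxillary" | "mandibular"
    side: str        # "left" | "right" (patient side)
    tooth_type: str


def _entry_from_fdi(class_index: int, fdi_code: str) -> FDIEntry:
    quadrant, position = int(fdi_code[0]), int(fdi_code[1])
    if quadrant not in (1, 2, 3, 4) or not 1 <= position <= 8:
        raise ValueError(f"invalid FDI code {fdi_code!r}")
    arch = "maxillary" if quadrant in (1, 2) else "mandibular"
    side = "right" if quadrant in (1, 4) else "left"
    return FDIEntry(class_index, fdi_code, arch, side, _TOOTH_TYPES[position - 1])


@dataclass(frozen=True)
class FDISchema:
    """Bijection between label-map class indices 1..32 and FDI tooth codes."""

    entries: tuple[FDIEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != 32:
            raise ValueError("FDI schema must contain exactly 32 entries")
        indices = {e.class_index for e in self.entries}
        codes = {e.fdi_code for e in self.entries}
        if indices != set(range(1, 33)):
            raise ValueError("class indices must be exactly 1..32")
        expected = {f"{q}{p}" for q in (1, 2, 3, 4) for p in range(1, 9)}
        if codes != expected:
            raise ValueError("FDI codes must cover all 32 permanent teeth")

    @classmethod
    def default(cls) -> "FDISchema":
        return cls.from_table(DEFAULT_SCHEMA_TABLE)

    @classmethod
    def from_table(cls, text: str) -> "FDISchema":
        """Parse a plain-text table of ``class_index<TAB>fdi_code`` lines."""
        entries = []
        for line in text.strip().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx_s, code = line.split()
            entries.append(_entry_from_fdi(int(idx_s), code))
        return cls(tuple(sorted(entries, key=lambda e: e.class_index)))

    @classmethod
    def from_file(cls, path: str | Path) -> "FDISchema":
        return cls.from_table(Path(path).read_text())

    def to_table(self) -> str:
        return "\n".join(f"{e.class_index}\t{e.fdi_code}" for e in self.entries)

    def lookup(self, class_index: int) -> FDIEntry:
        if not 1 <= int(class_index) <= 32:
            raise ValueError(
                f"class index {class_index} out of range 1..32 (0 is background)"
            )
        return self.entries[int(class_index) - 1]

    def class_of(self, fdi_code: str | int) -> int:
        code = str(fdi_code)
        for e in self.entries:
            if e.fdi_code == code:
                return e.class_index
        raise KeyError(f"unknown FDI code {fdi_code!r}")


def fdi_lookup(class_index: int, schema: FDISchema | None = None) -> FDIEntry:
    """Descriptor (fdi_code, arch, side, tooth_type) for a class index 1..32."""
    schema = schema or FDISchema.default()
    return schema.lookup(class_index)


@dataclass
class LabelMap:
    """2-D integer raster of per-pixel tooth class (0 = background)."""

    pixels: np.ndarray
    schema: FDISchema = field(default_factory=FDISchema.default)
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("label map must be a single-channel 2-D raster")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("label map pixels must be integers")
        bad = np.setdiff1d(np.unique(self.pixels), np.arange(N_CLASSES))
        if bad.size:
            raise ValueError(f"class out of schema: values {bad.tolist()} exceed 0..32")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def present_classes(self) -> list[int]:
        """Nonzero class indices present in the map, ascending."""
        vals = np.unique(self.pixels)
        return [int(v) for v in vals if v != 0]


@dataclass
class GrayImage:
    """Single-channel grayscale image with intensities in [0, 1]."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("grayscale image must be single-channel 2-D")


def read_labelmap(
    path: str | Path, schema: FDISchema | None = None, image_id: str | None = None
) -> LabelMap:
    """Read an 8/16-bit single-channel PNG or PGM raster as a label map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: multi-channel input; label maps are single-channel")
    return LabelMap(
        arr.astype(np.int32),
        schema or FDISchema.default(),
        image_id if image_id is not None else path.stem,
    )


def write_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    """Write a label map losslessly; round-trips bit-exactly through read."""
    path = Path(path)
    iio.imwrite(path, labelmap.pixels.astype(np.uint8))


def read_gray(path: str | Path, image_id: str | None = None) -> GrayImage:
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel grayscale input")
    return GrayImage(arr, image_id if image_id is not None else Path(path).stem)


def _minmax(pix: np.ndarray) -> np.ndarray:
    lo, hi = float(pix.min()), float(pix.max())
    if hi == lo:
        warnings.warn("constant image: min-max normalization degenerate, returning zeros")
        return np.zeros_like(pix, dtype=float)
    return (pix - lo) / (hi - lo)


def preprocess(image: GrayImage | LabelMap | np.ndarray) -> GrayImage | LabelMap:
    """Resample to 512 x 1024 and, for grayscale, min-max normalize to [0, 1].

    Grayscale rasters are resampled bilinearly; label maps use nearest
    neighbor so that no class value absent from the input can appear.
    A bare ndarray is treated as a raw grayscale raster.
    """
    if isinstance(image, LabelMap):
        if image.pixels.size == 0:
            raise ValueError("zero-size input")
        if image.shape == TARGET_SHAPE:
            return image
        out = resize(
            image.pixels, TARGET_SHAPE, order=0, preserve_range=True,
            anti_aliasing=False,
        ).astype(image.pixels.dtype)
        return LabelMap(out, image.schema, image.image_id)

    if isinstance(image, np.ndarray):
        image = GrayImage(image)
    if image.pixels.size == 0:
        raise ValueError("zero-size input")
    pix = image.pixels
    if pix.shape != TARGET_SHAPE:
        pix = resize(pix, TARGET_SHAPE, order=1, preserve_range=True,
                     anti_aliasing=False)
    return GrayImage(_minmax(pix), image.image_id)
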