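"""Tooth long-axis angulation from second-order central moments.

The measurement pipeline for one tooth class:

1. instance extraction — 8-connected component analysis on the class-specific
   binary mask; the largest component is kept;
2. initial principal-axis orientation theta from the second-order central
   moments of the pixel region;
3. orientation-aware apical exclusion — pixels are projected onto the initial
   principal axis (sign fixed so the axis points toward increasing row index,
   i.e. down the image) and the apical 22% of the extent is removed: the
   minimum-projection end for maxillary teeth (apices point at the image top)
   and the maximum-projection end for mandibular teeth;
4. the orientation is recomputed on the trimmed region and reported in signed
   degrees as the deviation of the long axis from the vertical image axis.

Sign convention: the angle is positive when the occlusal end of the axis
deviates toward increasing column index.  Because the occlusal end points
down the image for maxillary teeth and up for mandibular teeth, the raw
from-vertical orientation is negated for the mandibular arch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .labelmaps import FDISchema, LabelMap

logger = logging.getLogger(__name__)

#: Default apical fraction excluded along the principal axis.
DEFAULT_APICAL_FRACTION: float = 0.22

#: Smallest pixel count accepted as a tooth instance at 512x1024.
DEFAULT_MIN_PIXELS: int = 50

#: Tooth types measured by default: posterior selection, third molars omitted.
DEFAULT_SELECTION: tuple[str, ...] = (
    "canine",
    "first premolar",
    "second premolar",
    "first molar",
    "second molar",
)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class DegenerateRegionError(ValueError):
    """Raised when a region is too small or collapses under trimming."""


@dataclass
class ToothInstance:
    """One connected pixel region of a single tooth class.

    Central moments are in pixel^2 units with rows as the first coordinate:
    mu20 = sum (r - rbar)^2, mu02 = sum (c - cbar)^2, mu11 = the cross term.
    """

    class_index: int
    rows: np.ndarray
    cols: np.ndarray
    centroid: tuple[float, float] = field(init=False)
    mu20: float = field(init=False)
    mu02: float = field(init=False)
    mu11: float = field(init=False)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        if self.rows.shape != self.cols.shape or self.rows.ndim != 1:
            raise ValueError("rows and cols must be matching 1-D arrays")
        if self.rows.size == 0:
            raise ValueError("instance has no pixels")
        rbar = float(self.rows.mean())
        cbar = float(self.cols.mean())
        dr = self.rows - rbar
        dc = self.cols - cbar
        self.centroid = (rbar, cbar)
        self.mu20 = float(dr @ dr)
        self.mu02 = float(dc @ dc)
        self.mu11 = float(dr @ dc)

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.rows, self.cols] = True
        return out


@dataclass
class AngulationRecord:
    """Per-tooth measured long-axis angle in degrees with provenance."""

    image_id: str
    fdi_code: str
    angle_deg: float
    n_pixels_total: int
    n_pixels_retained: int
    degenerate_flag: bool = False
    apical_fraction: float = DEFAULT_APICAL_FRACTION

    @property
    def angle_abs_deg(self) -> float:
        return abs(self.angle_deg)

    @property
    def angle_vs_border_deg(self) -> float:
        return angle_vs_reference_border(self.angle_deg)


@dataclass
class MeasurementSet:
    """All angulation records for one image."""

    image_id: str
    records: list[AngulationRecord]
    tooth_selection: tuple[str, ...] = DEFAULT_SELECTION

    def to_dataframe(self) -> pd.DataFrame:
        return records_to_dataframe(self.records)


def extract_instances(
    labelmap: LabelMap, min_pixels: int = DEFAULT_MIN_PIXELS
) -> list[ToothInstance]:
    """8-connected component extraction per nonzero class.

    For each class the largest component is retained; smaller fragments are
    logged and dropped.  Classes whose largest component has fewer than
    ``min_pixels`` pixels are discarded entirely.
    """
    pixels = labelmap.pixels
    instances: list[ToothInstance] = []
    for cls in labelmap.present_classes():
        rr, cc = np.nonzero(pixels == cls)
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        crop = pixels[r0:r1, c0:c1] == cls
        labeled, n_comp = ndimage.label(crop, structure=_EIGHT_CONNECTED)
        if n_comp > 1:
            sizes = ndimage.sum_labels(crop, labeled, index=np.arange(1, n_comp + 1))
            keep = int(np.argmax(sizes)) + 1
            logger.warning(
                "class %d: %d fragments, keeping largest (%d px), dropping %d px",
                cls, n_comp, int(sizes[keep - 1]), int(sizes.sum() - sizes[keep - 1]),
            )
            crop = labeled == keep
        kr, kc = np.nonzero(crop)
        if kr.size < min_pixels:
            logger.warning("class %d: %d px below min_pixels=%d, discarded",
                           cls, kr.size, min_pixels)
            continue
        instances.append(ToothInstance(cls, kr + r0, kc + c0))
    return instances


def _orientation_from_moments(mu20: float, mu02: float, mu11: float) -> tuple[float, bool]:
    """Principal-axis orientation from the vertical axis, radians, (-pi/2, pi/2].

    Returns (theta, degenerate).  theta = 0.5 * atan2(2*mu11, mu20 - mu02):
    zero for a region elongated along image rows (a vertical tooth), pi/2 for
    one elongated along columns.  Isotropic moments have no principal axis;
    theta 0 is returned with the degenerate flag set.
    """
    scale = mu20 + mu02
    if abs(mu20 - mu02) <= 1e-12 * scale and abs(mu11) <= 1e-12 * scale:
        return 0.0, True
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    if theta <= -math.pi / 2:
        theta += math.pi
    return theta, False


def principal_orientation(inst: ToothInstance) -> float:
    """Orientation of the major principal axis, radians from vertical.

    Raises :class:`DegenerateRegionError` for regions with fewer than 3
    pixels; isotropic regions return 0 (query the flag via
    :func:`orientation_with_flag` when it matters).
    """
    theta, _ = orientation_with_flag(inst)
    return theta


def orientation_with_flag(inst: ToothInstance) -> tuple[float, bool]:
    if inst.n_pixels < 3:
        raise DegenerateRegionError("need at least 3 pixels to orient a region")
    return _orientation_from_moments(inst.mu20, inst.mu02, inst.mu11)


def apical_exclude(
    inst: ToothInstance,
    arch: str,
    fraction: float = DEFAULT_APICAL_FRACTION,
) -> ToothInstance:
    """Trim the apical ``fraction`` of the tooth extent along its long axis.

    Pixels are projected onto the unit vector of the instance's initial
    principal axis, with the axis sign fixed so the positive direction points
    toward increasing row index (down the image).  Maxillary apices then sit
    at the minimum projection values and mandibular apices at the maximum, so
    the apical end is the low-projection tail for the maxilla and the
    high-projection tail for the mandible.  Boundary pixels whose projection
    equals the cutoff are retained, which makes ``fraction = 0`` the identity.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("apical fraction must be in [0, 0.5)")
    if arch not in ("maxillary", "mandibular"):
        raise ValueError(f"unknown arch {arch!r}")
    if fraction == 0:
        return inst
    theta, degenerate = orientation_with_flag(inst)
    # axis unit vector (row, col); cos(theta) >= 0 on (-pi/2, pi/2] keeps the
    # row component non-negative (pointing down); a perfectly horizontal axis
    # degenerates to the column direction.
    u = (math.cos(theta), math.sin(theta))
    proj = inst.rows * u[0] + inst.cols * u[1]
    p_min, p_max = float(proj.min()), float(proj.max())
    extent = p_max - p_min
    if arch == "maxillary":
        keep = proj >= p_min + fraction * extent
    else:
        keep = proj <= p_max - fraction * extent
    if not keep.any():
        raise DegenerateRegionError("apical exclusion removed every pixel")
    return ToothInstance(inst.class_index, inst.rows[keep], inst.cols[keep])


def measure_angle(trimmed: ToothInstance, arch: str = "maxillary") -> tuple[float, bool]:
    """Signed long-axis angle in degrees for a (trimmed) region.

    Recomputes the principal orientation on the region as given and converts
    it to signed degrees in (-90, 90], positive when the occlusal end of the
    axis deviates toward increasing column index.  Returns
    ``(angle_deg, degenerate_flag)``; degenerate regions yield 0 with the
    flag set rather than an error.
    """
    theta, degenerate = orientation_with_flag(trimmed)
    angle = math.degrees(theta)
    if arch == "mandibular":
        angle = -angle
        if angle <= -90.0:
            angle += 180.0
    return angle, degenerate


def angle_vs_reference_border(angle_deg: float, arch: str = "maxillary") -> float:
    """Angle relative to the horizontal film border, degrees in [0, 90].

    The upper image border is the maxillary reference line and the lower
    border the mandibular one; both are horizontal and parallel to the image
    x-axis, so the border angle is the complement ``90 - |angle|`` of the
    from-vertical angle for either arch.  The sign of the deviation is
    carried separately by the signed ``angle_deg`` itself.
    """
    if not -90 < angle_deg <= 90:
        raise ValueError("angle_deg must lie in (-90, 90]")
    return 90.0 - abs(angle_deg)


def measure_image(
    labelmap: LabelMap,
    schema: FDISchema | None = None,
    selection: Sequence[str] = DEFAULT_SELECTION,
    fraction: float = DEFAULT_APICAL_FRACTION,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> MeasurementSet:
    """Run the full pipeline on every selected tooth present in the image.

    Per-tooth failures (degenerate geometry, pathological trims) produce
    flagged records rather than aborting the batch.  Records are sorted by
    FDI code; absent teeth produce no record.
    """
    schema = schema or labelmap.schema
    selection_set = set(selection)
    records: list[AngulationRecord] = []
    for inst in extract_instances(labelmap, min_pixels=min_pixels):
        entry = schema.lookup(inst.class_index)
        if entry.tooth_type not in selection_set:
            continue
        try:
            trimmed = apical_exclude(inst, entry.arch, fraction)
            angle, degenerate = measure_angle(trimmed, entry.arch)
            retained = trimmed.n_pixels
        except DegenerateRegionError as exc:
            logger.warning("tooth %s: %s; recording flagged zero angle",
                           entry.fdi_code, exc)
            angle, degenerate, retained = 0.0, True, inst.n_pixels
        records.append(
            AngulationRecord(
                image_id=labelmap.image_id,
                fdi_code=entry.fdi_code,
                angle_deg=angle,
                n_pixels_total=inst.n_pixels,
                n_pixels_retained=retained,
                degenerate_flag=degenerate,
                apical_fraction=fraction,
            )
        )
    records.sort(key=lambda r: r.fdi_code)
    return MeasurementSet(labelmap.image_id, records, tuple(selection))


# ---------------------------------------------------------------------------
# Record (de)serialization

CSV_COLUMNS = [
    "image_id",
    "fdi_code",
    "angle_deg",
    "angle_abs_deg",
    "angle_vs_border_deg",
    "n_pixels_total",
    "n_pixels_retained",
    "degenerate_flag",
]


def records_to_dataframe(records: Iterable[AngulationRecord]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id,
            "fdi_code": r.fdi_code,
            "angle_deg": r.angle_deg,
            "angle_abs_deg": r.angle_abs_deg,
            "angle_vs_border_deg": r.angle_vs_border_deg,
            "n_pixels_total": r.n_pixels_total,
            "n_pixels_retained": r.n_pixels_retained,
            "degenerate_flag": r.degenerate_flag,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_records_csv(records: Iterable[AngulationRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "fdi_code": str})
    missing = set(("image_id", "fdi_code", "angle_deg")) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df
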