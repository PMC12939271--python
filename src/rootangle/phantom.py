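"""Synthetic panoramic phantoms with known per-tooth long-axis angles.

The generator emulates what the angulation pipeline actually consumes — a
33-class label map of a full permanent dentition at 512 x 1024 — with exact
ground truth for every tooth's long-axis angle.  Teeth are stylized capsule
shafts (a rounded rectangle along the long axis), optionally with a deflected
apical segment ("hook") emulating root curvature and dilaceration; anatomical
crown/root morphology is deliberately not modelled, since the measured
quantity depends only on elongation and apical geometry.

Ground-truth angles use the same sign convention as the measurement pipeline:
positive when the occlusal end of the axis deviates toward increasing column
index.  Apices point toward row 0 for maxillary teeth and toward the last
row for mandibular teeth.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .labelmaps import FDISchema, LabelMap, TARGET_SHAPE

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Arch layout: editable configuration of the stylized dentition.
# Indexed by FDI position 1..8 (central incisor .. third molar).

ARCH_LAYOUT = {
    # horizontal distance of each tooth center from the facial midline (px)
    "col_offsets": [28, 82, 140, 200, 260, 324, 392, 454],
    # occlusal-plane curvature: vertical rise toward the distal ends (px)
    "occlusal_rise": [0, 2, 5, 9, 14, 20, 27, 34],
    # shaft length crown-anchor to apex (px)
    "shaft_lengths": [100, 95, 125, 110, 110, 115, 110, 95],
    # shaft width (px)
    "shaft_widths": [20, 16, 18, 22, 22, 32, 30, 26],
    # base long-axis tilt magnitude (deg); apices lean away from the midline
    "base_angles": [1.0, 2.0, 5.0, 4.0, 4.0, 3.0, 2.0, 1.0],
    # occlusal anchor rows at the midline for the two arches
    "maxillary_occlusal_row": 250,
    "mandibular_occlusal_row": 282,
    "midline_col": 512,
}


@dataclass
class ToothSpec:
    """Geometry of one synthetic tooth."""

    fdi_code: str
    crown_center: tuple[float, float]          # occlusal anchor (row, col)
    shaft_length: float
    shaft_width: float
    true_angle_deg: float                      # signed, occlusal-end convention
    apical_hook_angle_deg: float = 0.0
    apical_hook_fraction: float = 0.2
    present: bool = True

    def __post_init__(self) -> None:
        if self.shaft_length < 40:
            raise ValueError("shaft_length must be at least 40 px")
        if abs(self.true_angle_deg) > 45:
            raise ValueError("|true_angle_deg| must not exceed 45")
        if not 0 <= self.apical_hook_fraction < 0.5:
            raise ValueError("apical_hook_fraction must be in [0, 0.5)")

    @property
    def arch(self) -> str:
        return "maxillary" if self.fdi_code[0] in "12" else "mandibular"


@dataclass
class PhantomSpec:
    """Full specification of one synthetic image."""

    teeth: list[ToothSpec]
    image_shape: tuple[int, int] = TARGET_SHAPE
    seed: int = 0
    image_id: str = ""

    def __post_init__(self) -> None:
        if len(self.teeth) > 32:
            raise ValueError("at most 32 teeth")
        if not self.image_id:
            self.image_id = f"phantom_{self.seed:05d}"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "image_shape": list(self.image_shape),
            "seed": self.seed,
            "image_id": self.image_id,
            "teeth": [asdict(t) for t in self.teeth],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PhantomSpec":
        s = str(text_or_path)
        if "\n" in s or s.lstrip().startswith("{"):
            text = s
        else:
            text = Path(s).read_text()
        payload = json.loads(text)
        teeth = [
            ToothSpec(**{**t, "crown_center": tuple(t["crown_center"])})
            for t in payload["teeth"]
        ]
        return cls(teeth, tuple(payload["image_shape"]), payload["seed"],
                   payload["image_id"])


def _rotate(v: tuple[float, float], deg: float) -> tuple[float, float]:
    a = math.radians(deg)
    return (v[0] * math.cos(a) - v[1] * math.sin(a),
            v[0] * math.sin(a) + v[1] * math.cos(a))


def _occlusal_direction(spec: ToothSpec) -> tuple[float, float]:
    """Unit vector along the long axis pointing toward the occlusal end."""
    a = math.radians(spec.true_angle_deg)
    if spec.arch == "maxillary":
        return (math.cos(a), math.sin(a))        # occlusal end points down
    return (-math.cos(a), math.sin(a))           # occlusal end points up


def _capsule_mask(shape, p0, p1, radius) -> np.ndarray:
    """Boolean mask of pixels within ``radius`` of segment p0-p1."""
    r0 = int(max(0, math.floor(min(p0[0], p1[0]) - radius - 1)))
    r1 = int(min(shape[0], math.ceil(max(p0[0], p1[0]) + radius + 2)))
    c0 = int(max(0, math.floor(min(p0[1], p1[1]) - radius - 1)))
    c1 = int(min(shape[1], math.ceil(max(p0[1], p1[1]) + radius + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = np.array(p1) - np.array(p0)
    seg_len2 = float(dr @ dr)
    wr = rr - p0[0]
    wc = cc - p0[1]
    t = np.clip((wr * dr[0] + wc * dr[1]) / max(seg_len2, 1e-12), 0.0, 1.0)
    d2 = (wr - t * dr[0]) ** 2 + (wc - t * dr[1]) ** 2
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = d2 <= radius ** 2
    return out


def rasterize_tooth(spec: ToothSpec, shape: tuple[int, int] = TARGET_SHAPE) -> np.ndarray:
    """Binary mask of one tooth: a capsule shaft plus an optional apical hook.

    The shaft runs from the occlusal anchor toward the apex along the true
    long axis; if ``apical_hook_angle_deg`` is nonzero, the apical
    ``apical_hook_fraction`` of the length is drawn as a second capsule
    segment deflected by that angle, joined continuously at the bend.
    """
    if not spec.present:
        return np.zeros(shape, dtype=bool)
    d_occ = np.array(_occlusal_direction(spec))
    apical = -d_occ
    occ = np.array(spec.crown_center, dtype=float)
    h = spec.apical_hook_fraction if spec.apical_hook_angle_deg != 0 else 0.0
    joint = occ + (1.0 - h) * spec.shaft_length * apical
    radius = spec.shaft_width / 2.0
    mask = _capsule_mask(shape, occ, joint, radius)
    endpoints = [occ, joint]
    if h > 0:
        hook_dir = np.array(_rotate(tuple(apical), spec.apical_hook_angle_deg))
        apex = joint + h * spec.shaft_length * hook_dir
        mask |= _capsule_mask(shape, joint, apex, radius)
        endpoints.append(apex)
    for p in endpoints:
        if not (radius <= p[0] <= shape[0] - 1 - radius
                and radius <= p[1] <= shape[1] - 1 - radius):
            raise ValueError(f"tooth {spec.fdi_code}: geometry out of image bounds")
    return mask


def generate_phantom(
    spec: PhantomSpec, schema: FDISchema | None = None
) -> tuple[LabelMap, pd.DataFrame]:
    """Render a phantom spec into a label map plus its ground-truth table.

    Deterministic given the spec.  Tooth masks must be pairwise disjoint;
    any overlap raises.  The truth table has one row per present tooth:
    (image_id, fdi_code, true_angle_deg, n_pixels).
    """
    schema = schema or FDISchema.default()
    pixels = np.zeros(spec.image_shape, dtype=np.int32)
    rows = []
    for tooth in spec.teeth:
        if not tooth.present:
            continue
        mask = rasterize_tooth(tooth, spec.image_shape)
        if (pixels[mask] != 0).any():
            raise ValueError(f"tooth {tooth.fdi_code} overlaps a previous tooth")
        pixels[mask] = schema.class_of(tooth.fdi_code)
        rows.append({
            "image_id": spec.image_id,
            "fdi_code": tooth.fdi_code,
            "true_angle_deg": tooth.true_angle_deg,
            "n_pixels": int(mask.sum()),
        })
    truth = pd.DataFrame(rows, columns=["image_id", "fdi_code",
                                        "true_angle_deg", "n_pixels"])
    return LabelMap(pixels, schema, spec.image_id), truth


def default_dentition(
    seed: int = 0,
    angle_noise_sd: float = 2.5,
    hook_prob: float = 0.3,
    missing: tuple[str, ...] = (),
    layout: dict = ARCH_LAYOUT,
) -> PhantomSpec:
    """Full 32-tooth dentition on two arch curves with plausible angulations.

    Each tooth's true angle is its arch-layout base angle (apex leaning away
    from the midline) plus Normal(0, ``angle_noise_sd``) degrees, clipped to
    twice the noise SD so neighbouring teeth cannot collide.  Apical hooks
    are assigned independently with probability ``hook_prob``; a hook
    deflects the apical 20% of the shaft by 10–30 degrees, always curving
    distally (away from the midline) — the common direction of root
    dilaceration, which also keeps hooked neighbours disjoint.  FDI codes
    listed in ``missing`` are marked absent.
    """
    rng = np.random.default_rng(seed)
    teeth: list[ToothSpec] = []
    for quadrant in (1, 2, 3, 4):
        # quadrants 1 & 4 are the patient's right: viewer-left on the film
        col_sign = -1 if quadrant in (1, 4) else 1
        maxillary = quadrant in (1, 2)
        for pos in range(1, 9):
            i = pos - 1
            col = layout["midline_col"] + col_sign * layout["col_offsets"][i]
            rise = layout["occlusal_rise"][i]
            if maxillary:
                row = layout["maxillary_occlusal_row"] - rise
            else:
                row = layout["mandibular_occlusal_row"] + rise
            # apex away from midline: positive signed angle on the viewer-left
            base = -col_sign * layout["base_angles"][i]
            noise = float(np.clip(rng.normal(0.0, angle_noise_sd),
                                  -2 * angle_noise_sd, 2 * angle_noise_sd))
            hook = 0.0
            if rng.random() < hook_prob:
                # distal deflection: positive rotation moves a maxillary apex
                # toward +col and a mandibular apex toward -col
                distal = -col_sign if maxillary else col_sign
                hook = float(rng.uniform(10.0, 30.0)) * distal
            code = f"{quadrant}{pos}"
            teeth.append(ToothSpec(
                fdi_code=code,
                crown_center=(float(row), float(col)),
                shaft_length=float(layout["shaft_lengths"][i]),
                shaft_width=float(layout["shaft_widths"][i]),
                true_angle_deg=base + noise,
                apical_hook_angle_deg=hook,
                present=code not in set(missing),
            ))
    return PhantomSpec(teeth, TARGET_SHAPE, seed)


# ---------------------------------------------------------------------------
# Repeat-acquisition perturbation

def _transform_angle(angle_deg: float, arch: str, matrix: np.ndarray) -> float:
    """Push a signed occlusal-convention angle through a linear map."""
    raw = math.radians(angle_deg if arch == "maxillary" else -angle_deg)
    v = matrix @ np.array([math.cos(raw), math.sin(raw)])
    if v[0] < 0:
        v = -v
    new_raw = math.degrees(math.atan2(v[1], v[0]))
    if new_raw <= -90.0:
        new_raw += 180.0
    out = new_raw if arch == "maxillary" else -new_raw
    if out <= -90.0:
        out += 180.0
    return out


def perturb_acquisition(
    labelmap: LabelMap,
    truth: pd.DataFrame,
    rotation_deg: float = 0.0,
    shear: float = 0.0,
    image_id: str | None = None,
) -> tuple[LabelMap, pd.DataFrame]:
    """Emulate a repeat acquisition: in-plane rotation plus horizontal shear.

    The label map is resampled with nearest neighbor (label integrity) about
    the image center; the truth angles are updated analytically through the
    same linear map, so re-measuring the perturbed map should reproduce the
    perturbed truth.  A positive rotation increases every raw from-vertical
    angle by ``rotation_deg``; in the signed occlusal-end convention that is
    +rotation for maxillary teeth and -rotation for mandibular teeth.  Teeth
    pushed entirely out of frame are dropped from the truth with a warning.
    """
    if abs(rotation_deg) > 10:
        raise ValueError("|rotation_deg| must be at most 10")
    beta = math.radians(rotation_deg)
    rot = np.array([[math.cos(beta), -math.sin(beta)],
                    [math.sin(beta), math.cos(beta)]])
    shr = np.array([[1.0, 0.0], [shear, 1.0]])
    m = shr @ rot
    if rotation_deg == 0 and shear == 0:
        new_pixels = labelmap.pixels.copy()
    else:
        center = (np.array(labelmap.shape) - 1) / 2.0
        minv = np.linalg.inv(m)
        new_pixels = ndimage.affine_transform(
            labelmap.pixels, minv, offset=center - minv @ center,
            order=0, mode="constant", cval=0, output=np.int32,
        )
    image_id = image_id or f"{labelmap.image_id}_r{rotation_deg:g}_s{shear:g}"
    new_map = LabelMap(new_pixels, labelmap.schema, image_id)
    counts = dict(zip(*np.unique(new_pixels, return_counts=True)))
    rows = []
    for _, row in truth.iterrows():
        cls = labelmap.schema.class_of(row["fdi_code"])
        n_pix = int(counts.get(cls, 0))
        if n_pix == 0:
            warnings.warn(f"tooth {row['fdi_code']} left the frame, dropped")
            continue
        arch = labelmap.schema.lookup(cls).arch
        rows.append({
            "image_id": image_id,
            "fdi_code": row["fdi_code"],
            "true_angle_deg": _transform_angle(row["true_angle_deg"], arch, m),
            "n_pixels": n_pix,
        })
    return new_map, pd.DataFrame(rows, columns=truth.columns)
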