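"""Per-subject torque measurements.

Three features quantify the counter-clockwise cerebral torque, each as a
signed left-minus-right quantity on an MSP-aligned brain:

* **petalia** — protrusion of one frontal/occipital pole beyond the other
  along the antero-posterior (y) axis: y(left pole) - y(right pole), mm.
* **shift** — dorso-ventral (z) displacement of the same pole vertices:
  z(left pole) - z(right pole), mm.
* **bending** — tilt of the inter-hemispheric fissure in the frontal and
  occipital quarters: the angle between a fitted medial plane's normal and
  the x-axis, signed so that bending toward the subject's right is
  positive, averaged over the two hemispheres, degrees.

The human-typical pattern is right-frontal/left-occipital (RF/LO) petalia
(frontal < 0, occipital < 0), a downward shift of the left occipital pole
(occipital shift < 0), and rightward occipital bending (> 0).

Linear dimensions (length/height/width of each hemisphere and of the whole
surface) come from axis-aligned bounding boxes, corrected to native space
by the subject's uniform scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alignment import BrainSurface, align_to_msp, fit_plane, medial_vertices
from .geometry import TriMesh, bounding_box, extract_pole

__all__ = [
    "DimensionRecord",
    "Configuration",
    "TorqueRecord",
    "measure_dimensions",
    "measure_petalia",
    "measure_shift",
    "measure_bending",
    "classify_configuration",
    "measure_subject",
]

CONFIGURATIONS = ("LF/LO", "LF/RO", "RF/LO", "RF/RO")


def _require_aligned(brain: BrainSurface, what: str) -> None:
    if not brain.aligned:
        raise ValueError(f"{what} requires an MSP-aligned brain; "
                         "run align_to_msp first")


@dataclass(frozen=True)
class DimensionRecord:
    """Scale-corrected linear dimensions (mm) and their asymmetries."""

    left_length: float
    left_height: float
    left_width: float
    right_length: float
    right_height: float
    right_width: float
    whole_length: float
    whole_height: float
    whole_width: float

    @property
    def length_width_ratio(self) -> float:
        return self.whole_length / self.whole_width

    @property
    def height_width_ratio(self) -> float:
        return self.whole_height / self.whole_width

    @property
    def delta_length(self) -> float:
        """L - R antero-posterior length asymmetry, mm."""
        return self.left_length - self.right_length

    @property
    def delta_height(self) -> float:
        return self.left_height - self.right_height

    @property
    def delta_width(self) -> float:
        return self.left_width - self.right_width


@dataclass(frozen=True)
class Configuration:
    """A frontal/occipital quadrant label such as "RF/LO".

    ``tie`` marks that one of the two inputs was exactly zero and the side
    was assigned by the deterministic tie-break (frontal -> R, occipital
    -> L) rather than by a measured sign.
    """

    label: str
    tie: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label + (" (tie)" if self.tie else "")


@dataclass(frozen=True)
class TorqueRecord:
    """All torque measurements for one subject."""

    subject_id: str
    species: str
    sex: Optional[str]
    petalia_frontal: float
    petalia_occipital: float
    shift_frontal: float
    shift_occipital: float
    bending_frontal: float
    bending_occipital: float
    config_petalia: Configuration
    config_shift: Configuration
    config_bending: Configuration
    dimensions: DimensionRecord


def measure_dimensions(brain: BrainSurface) -> DimensionRecord:
    """Bounding-box dimensions of the left, right and whole surface.

    The three boxes are constructed independently; the whole-surface box
    encloses the union of both hemispheres.  All extents are multiplied by
    the subject scale factor.
    """
    _require_aligned(brain, "measure_dimensions")
    lbox = bounding_box(brain.left, scale=brain.scale)
    rbox = bounding_box(brain.right, scale=brain.scale)
    union = TriMesh(brain.all_vertices,
                    np.array([[0, 1, 2]]), side="whole")
    wbox = bounding_box(union, scale=brain.scale)
    return DimensionRecord(
        left_length=lbox.length, left_height=lbox.height, left_width=lbox.width,
        right_length=rbox.length, right_height=rbox.height, right_width=rbox.width,
        whole_length=wbox.length, whole_height=wbox.height, whole_width=wbox.width,
    )


def _pole_pair(brain: BrainSurface, direction: str) -> tuple[np.ndarray, np.ndarray]:
    return (extract_pole(brain.left, direction),
            extract_pole(brain.right, direction))


def measure_petalia(brain: BrainSurface) -> tuple[float, float]:
    """(frontal, occipital) petalia in native mm.

    Frontal = y(left anterior pole) - y(right anterior pole); negative
    means the right frontal pole protrudes further forward.  Occipital
    uses the posterior poles; negative means the left occipital pole
    protrudes further backward.
    """
    _require_aligned(brain, "measure_petalia")
    la, ra = _pole_pair(brain, "anterior")
    lp, rp = _pole_pair(brain, "posterior")
    return (brain.scale * float(la[1] - ra[1]),
            brain.scale * float(lp[1] - rp[1]))


def measure_shift(brain: BrainSurface) -> tuple[float, float]:
    """(frontal, occipital) dorso-ventral shift in native mm.

    L - R of the z-coordinates of the same pole vertices used for petalia;
    negative occipital shift means the left occipital pole sits lower.
    """
    _require_aligned(brain, "measure_shift")
    la, ra = _pole_pair(brain, "anterior")
    lp, rp = _pole_pair(brain, "posterior")
    return (brain.scale * float(la[2] - ra[2]),
            brain.scale * float(lp[2] - rp[2]))


def _signed_bending(normal: np.ndarray, region: str) -> float:
    # canonical normal has x >= 0; magnitude is the angle to the x-axis
    angle = np.degrees(np.arccos(np.clip(normal[0], -1.0, 1.0)))
    sign = np.sign(normal[1])
    if region == "frontal":
        sign = -sign
    return float(sign * angle)


def measure_bending(brain: BrainSurface, theta_max: float = 40.0,
                    quarter_fraction: float = 0.25) -> tuple[float, float]:
    """(frontal, occipital) bending angles in degrees, rightward positive.

    Per hemisphere, medial-surface vertices falling in the first (frontal)
    and last (occipital) ``quarter_fraction`` of the whole-brain antero-
    posterior extent are fitted with a total-least-squares plane; the
    bending angle is the angle between that plane's normal and the x-axis.
    The sign comes from the normal's y-component so that a fissure bending
    toward the subject's right at its frontal or occipital extreme is
    positive; the two hemispheres' angles are averaged per region.
    """
    _require_aligned(brain, "measure_bending")
    if not 0 < quarter_fraction <= 0.5:
        raise ValueError("quarter_fraction must be in (0, 0.5]")
    y_lo, y_hi = brain.y_range()
    span = y_hi - y_lo
    angles = {"frontal": [], "occipital": []}
    for mesh in (brain.left, brain.right):
        sel = medial_vertices(mesh, theta_max=theta_max)
        pts = mesh.vertices[sel.indices]
        bands = {
            "frontal": pts[pts[:, 1] >= y_hi - quarter_fraction * span],
            "occipital": pts[pts[:, 1] <= y_lo + quarter_fraction * span],
        }
        for region, band in bands.items():
            if len(band) < 3:
                raise ValueError(
                    f"only {len(band)} medial vertices in the {region} "
                    f"quarter of the {mesh.side} hemisphere"
                )
            plane = fit_plane(band)
            angles[region].append(_signed_bending(plane.normal, region))
    return (float(np.mean(angles["frontal"])),
            float(np.mean(angles["occipital"])))


def classify_configuration(frontal: float, occipital: float,
                           feature: str) -> Configuration:
    """Quadrant label (LF/RF x LO/RO) for one torque feature.

    For petalia and shift the letter names the dominant side of the pole
    asymmetry: frontal > 0 (left pole leads / sits higher) is LF, else RF;
    occipital < 0 (left pole protrudes backward / sits lower) is LO, else
    RO.  For bending the letter names the direction of the bend: rightward
    (positive) frontal or occipital bending is RF or RO.  Exact zeros are
    resolved toward RF (frontal) and LO (occipital) and flagged as ties.
    """
    if feature not in ("petalia", "shift", "bending"):
        raise ValueError(f"unknown feature {feature!r}")
    if feature == "bending":
        f_label = "RF" if frontal >= 0 else "LF"
        o_label = "RO" if occipital > 0 else "LO"
    else:
        f_label = "LF" if frontal > 0 else "RF"
        o_label = "LO" if occipital <= 0 else "RO"
    return Configuration(label=f"{f_label}/{o_label}",
                         tie=(frontal == 0 or occipital == 0))


def measure_subject(brain: BrainSurface, theta_max: float = 40.0,
                    central_fraction: float = 0.5,
                    quarter_fraction: float = 0.25,
                    tol: float = 0.01, max_iter: int = 5) -> TorqueRecord:
    """Full torque record for one subject (aligning first if needed)."""
    if not brain.aligned:
        brain = align_to_msp(brain, tol=tol, max_iter=max_iter,
                             central_fraction=central_fraction,
                             theta_max=theta_max)
    pet = measure_petalia(brain)
    shf = measure_shift(brain)
    bend = measure_bending(brain, theta_max=theta_max,
                           quarter_fraction=quarter_fraction)
    return TorqueRecord(
        subject_id=brain.subject_id,
        species=brain.species,
        sex=brain.sex,
        petalia_frontal=pet[0], petalia_occipital=pet[1],
        shift_frontal=shf[0], shift_occipital=shf[1],
        bending_frontal=bend[0], bending_occipital=bend[1],
        config_petalia=classify_configuration(*pet, "petalia"),
        config_shift=classify_configuration(*shf, "shift"),
        config_bending=classify_configuration(*bend, "bending"),
        dimensions=measure_dimensions(brain),
    )
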