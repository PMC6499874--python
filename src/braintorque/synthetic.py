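"""Synthetic hemisphere pairs with known, injectable torque.

No per-subject surfaces are published for the MRI cohorts this pipeline
targets, so validation rests on simulated subjects whose ground truth is
known exactly.  Each hemisphere is a half-superellipsoid — the simplest
closed surface with brain-like proportions and a flat medial wall — cut at
the midline and offset laterally by a small gap so the two medial walls
are distinct, as the inter-hemispheric fissure keeps the real outer
surfaces apart.  Sulci are deliberately absent: the measurement pipeline
consumes morphologically closed outer surfaces on which gyrification has
already been filled in.

Torque is injected by construction so that a perfect measurement would
read back the requested parameters exactly:

* petalia / shift — smooth cosine-ramp displacement fields in y / z,
  split +-p/2 between the hemispheres and tapering to zero toward
  mid-brain so the central MSP band stays undeformed;
* bending — a y-graded lateral (x) displacement of the frontal / occipital
  quarter matching the tangent of the target angle, applied to both
  hemispheres so the fissure itself tilts;
* dimensional asymmetry — anisotropic scaling of the left hemisphere
  (about its medial wall in x, about its centre in y and z); the pole
  displacements this induces are compensated by the petalia/shift fields
  so the injected values remain the ground truth;
* a rigid mid-sagittal tilt and a spatially smooth Gaussian surface-noise
  field emulate the imperfect whole-head registration and the correlated
  segmentation error of real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as _dc_fields, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

import pandas as pd

from .alignment import BrainSurface
from .geometry import TriMesh, extract_pole, mirror_x
from . import reference

__all__ = [
    "TorqueParams",
    "CohortSpec",
    "make_hemisphere",
    "make_brain",
    "apply_torque",
    "sample_params",
    "simulate_cohort",
    "REGIMES",
]

#: Default semi-axes (x, y, z) in mm: hemisphere width, half-length,
#: half-height chosen so the whole synthetic brain has roughly human
#: whole-surface dimensions (~136 x 174 x 118 mm).
DEFAULT_SEMI_AXES = (67.0, 87.0, 59.0)
DEFAULT_EXPONENT = 2.5
DEFAULT_GAP = 1.0
#: Fraction of the antero-posterior extent over which the petalia/shift
#: displacement ramps from zero (at mid-brain) to full (at the pole).
TAPER_FRACTION = 0.4


@dataclass(frozen=True)
class TorqueParams:
    """Ground-truth deformation parameters for one synthetic subject.

    mm for petalia/shift and the dimensional deltas, degrees for the
    bending angles and the mid-sagittal tilt.  ``global_scale`` scales the
    whole geometry (brain size) without touching the injected asymmetries,
    which stay in absolute mm/degrees.
    """

    petalia_frontal: float = 0.0
    petalia_occipital: float = 0.0
    shift_frontal: float = 0.0
    shift_occipital: float = 0.0
    bend_frontal: float = 0.0
    bend_occipital: float = 0.0
    delta_length: float = 0.0
    delta_height: float = 0.0
    delta_width: float = 0.0
    msp_tilt: float = 0.0
    global_scale: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for f in _dc_fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise ValueError(f"{f.name} must be finite")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}


def _half_ball_mesh(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed unit half-ball surface on x >= 0: curved dome + flat cap at x = 0.

    Returns vertices on or inside the unit sphere (cap interior points have
    norm < 1) and outward-wound triangular faces.
    """
    m = int(np.ceil(resolution / 4) * 4)        # azimuth steps, multiple of 4
    n_rings = m // 2                            # polar rings apex -> rim
    n_cap = max(2, m // 4)                      # rim -> cap centre
    beta = 2 * np.pi * np.arange(m) / m
    cb, sb = np.cos(beta), np.sin(beta)

    ring_coords = []
    for i in range(1, n_rings + 1):             # curved dome rings
        alpha = 0.5 * np.pi * i / n_rings
        ring_coords.append(np.column_stack([np.full(m, np.cos(alpha)),
                                            np.sin(alpha) * cb,
                                            np.sin(alpha) * sb]))
    for k in range(1, n_cap):                   # shrinking cap rings at x = 0
        r = 1.0 - k / n_cap
        ring_coords.append(np.column_stack([np.zeros(m), r * cb, r * sb]))

    vertices = np.vstack([[[1.0, 0.0, 0.0]], *ring_coords, [[0.0, 0.0, 0.0]]])
    rings = [1 + i * m + np.arange(m) for i in range(len(ring_coords))]
    centre_idx = len(vertices) - 1

    faces = []
    first = rings[0]
    for j in range(m):                          # apex fan
        faces.append([0, first[j], first[(j + 1) % m]])
    for a, b in zip(rings[:-1], rings[1:]):     # quad strips
        for j in range(m):
            j2 = (j + 1) % m
            faces.append([a[j], b[j], b[j2]])
            faces.append([a[j], b[j2], a[j2]])
    last = rings[-1]
    for j in range(m):                          # cap centre fan
        faces.append([last[j], centre_idx, last[(j + 1) % m]])
    return vertices, np.asarray(faces, dtype=np.int64)


def _superellipsoid_map(unit_points: np.ndarray, semi_axes: np.ndarray,
                        exponent: float) -> np.ndarray:
    """Map unit-sphere directions onto the superellipsoid |x/a|^p + ... = 1."""
    u = unit_points
    return semi_axes * np.sign(u) * np.abs(u) ** (2.0 / exponent)


def make_hemisphere(side: str, semi_axes=DEFAULT_SEMI_AXES,
                    resolution: int = 48,
                    exponent: float = DEFAULT_EXPONENT,
                    gap: float = DEFAULT_GAP) -> TriMesh:
    """A closed half-superellipsoid hemisphere surface.

    The right hemisphere occupies x in [gap, gap + a_x]; the left is its
    exact mirror image, so a pair built with identical parameters is
    mirror-symmetric and has every torque metric equal to zero.  The flat
    medial wall sits at x = +-gap and plays the role of the hemisphere's
    inter-hemispheric (medial) surface.

    ``exponent`` >= 2 controls the squareness of the profile (2 is an
    ellipsoid); ``resolution`` sets the azimuthal vertex count (>= 16).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    if exponent < 2:
        raise ValueError("superellipse exponent must be >= 2")
    axes = np.asarray(semi_axes, dtype=float)
    if axes.shape != (3,) or np.any(axes <= 0):
        raise ValueError("semi_axes must be 3 positive reals")
    unit_v, faces = _half_ball_mesh(resolution)
    v = _superellipsoid_map(unit_v, axes, exponent)
    v[:, 0] += gap
    mesh = TriMesh(v, faces, side="right")
    return mirror_x(mesh) if side == "left" else mesh


def make_brain(semi_axes=DEFAULT_SEMI_AXES, resolution: int = 48,
               exponent: float = DEFAULT_EXPONENT, gap: float = DEFAULT_GAP,
               subject_id: str = "", species: str = "synthetic",
               sex: Optional[str] = None) -> BrainSurface:
    """A mirror-symmetric left/right pair (all torque metrics zero)."""
    return BrainSurface(
        left=make_hemisphere("left", semi_axes, resolution, exponent, gap),
        right=make_hemisphere("right", semi_axes, resolution, exponent, gap),
        subject_id=subject_id, species=species, sex=sex,
    )


def _cosine_ramp(y: np.ndarray, y_start: float, y_end: float) -> np.ndarray:
    """0 at y_start, 1 at y_end, smooth (zero-slope ends) in between."""
    s = np.clip((y - y_start) / (y_end - y_start), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * s))


def _scale_left(mesh: TriMesh, params: TorqueParams) -> TriMesh:
    """Anisotropic scaling of the left hemisphere for the dimensional deltas."""
    v = mesh.vertices.copy()
    lo, hi = v.min(axis=0), v.max(axis=0)
    ext = hi - lo
    if params.delta_width:
        wall = hi[0]  # medial wall (largest x of the left hemisphere)
        v[:, 0] = wall + (v[:, 0] - wall) * (1 + params.delta_width / ext[0])
    if params.delta_length:
        cy = 0.5 * (lo[1] + hi[1])
        v[:, 1] = cy + (v[:, 1] - cy) * (1 + params.delta_length / ext[1])
    if params.delta_height:
        cz = 0.5 * (lo[2] + hi[2])
        v[:, 2] = cz + (v[:, 2] - cz) * (1 + params.delta_height / ext[2])
    return mesh.with_vertices(v)


def _smooth_noise(points: np.ndarray, rng: np.random.Generator, sd: float,
                  n_waves: int = 24,
                  wavelengths: tuple[float, float] = (20.0, 50.0)) -> np.ndarray:
    """Spatially smooth Gaussian displacement field (random cosine sum).

    Surface-reconstruction error is spatially correlated, not independent
    per vertex; per-vertex white noise would let extreme-point (pole)
    measurements jump between distant near-tied vertices, which never
    happens with a smooth perturbation.  Each displacement component is a
    sum of ``n_waves`` random plane waves with wavelengths of a few cm,
    normalised so the pointwise amplitude is N(0, sd^2).
    """
    disp = np.empty_like(points)
    for c in range(3):
        dirs = rng.normal(size=(n_waves, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lam = rng.uniform(*wavelengths, n_waves)
        kvec = (2 * np.pi / lam)[:, None] * dirs
        phase = rng.uniform(0, 2 * np.pi, n_waves)
        disp[:, c] = (np.cos(points @ kvec.T + phase)
                      .sum(axis=1)) * sd * np.sqrt(2.0 / n_waves)
    return disp


def _restore_width(mesh: TriMesh, target_width: float) -> TriMesh:
    """Compress the lateral part of a hemisphere back to its pre-bend width.

    Bending pushes the medial wall past the midline, which widens that
    hemisphere's bounding box; to keep the dimensional ground truth
    independent of the bend parameters, the lateral 80% of the hemisphere
    (measured from its medial extreme) is compressed so the overall width
    returns to ``target_width``.  The medial wall itself — and with it the
    bend angle, the poles and the MSP — is untouched.
    """
    v = mesh.vertices
    x = v[:, 0]
    medial_is_max = mesh.side == "left"   # left hemisphere: medial wall at max x
    m = x.max() if medial_is_max else x.min()
    u = (m - x) if medial_is_max else (x - m)   # distance from medial extreme
    width = float(u.max())
    if width <= target_width:
        return mesh
    u1 = 0.2 * width
    f = (target_width - u1) / (width - u1)
    u_new = np.where(u > u1, u1 + (u - u1) * f, u)
    x_new = (m - u_new) if medial_is_max else (m + u_new)
    out = v.copy()
    out[:, 0] = x_new
    return mesh.with_vertices(out)


def apply_torque(brain: BrainSurface, params: TorqueParams,
                 quarter_fraction: float = 0.25) -> BrainSurface:
    """Deform a symmetric pair so its measured torque equals ``params``.

    Steps, in order: global size scaling; anisotropic left-hemisphere
    scaling (dimensional deltas); pole displacement fields for petalia and
    shift, with targets corrected for the pole motion the scaling step
    already caused; lateral quarter-band displacement for bending; rigid
    mid-sagittal tilt; Gaussian vertex noise.  The parameters are stored
    as ground truth in ``metadata["truth"]``.
    """
    left, right = brain.left, brain.right
    if params.global_scale != 1.0:
        left = left.with_vertices(left.vertices * params.global_scale)
        right = right.with_vertices(right.vertices * params.global_scale)
    left = _scale_left(left, params)

    # residual pole offsets after scaling, to be compensated by the fields
    pf0 = extract_pole(left, "anterior")[1] - extract_pole(right, "anterior")[1]
    po0 = extract_pole(left, "posterior")[1] - extract_pole(right, "posterior")[1]
    sf0 = extract_pole(left, "anterior")[2] - extract_pole(right, "anterior")[2]
    so0 = extract_pole(left, "posterior")[2] - extract_pole(right, "posterior")[2]

    all_y = np.concatenate([left.vertices[:, 1], right.vertices[:, 1]])
    y_lo, y_hi = float(all_y.min()), float(all_y.max())
    span = y_hi - y_lo

    # The poles are by definition the y-extremes of each hemisphere, so
    # L-R length asymmetry is *identically* frontal minus occipital petalia
    # (the published human means obey this: -0.67 - (-1.58) ~ 0.92).  A
    # requested delta_length therefore acts as a symmetric stretch on top
    # of the petalia offsets, and the realized pole values become the
    # stored ground truth.
    pf_target = params.petalia_frontal + 0.5 * params.delta_length
    po_target = params.petalia_occipital - 0.5 * params.delta_length

    def pole_fields(mesh: TriMesh, sign: float) -> TriMesh:
        v = mesh.vertices.copy()
        w_f = _cosine_ramp(v[:, 1], y_hi - TAPER_FRACTION * span, y_hi)
        w_o = _cosine_ramp(v[:, 1], y_lo + TAPER_FRACTION * span, y_lo)
        v[:, 1] += sign * 0.5 * ((pf_target - pf0) * w_f
                                 + (po_target - po0) * w_o)
        v[:, 2] += sign * 0.5 * ((params.shift_frontal - sf0) * w_f
                                 + (params.shift_occipital - so0) * w_o)
        return mesh.with_vertices(v)

    left = pole_fields(left, +1.0)
    right = pole_fields(right, -1.0)

    if params.bend_frontal or params.bend_occipital:
        all_y = np.concatenate([left.vertices[:, 1], right.vertices[:, 1]])
        y_lo, y_hi = float(all_y.min()), float(all_y.max())
        span = y_hi - y_lo
        yq_f = y_hi - quarter_fraction * span
        yq_o = y_lo + quarter_fraction * span
        tf = np.tan(np.radians(params.bend_frontal))
        to = np.tan(np.radians(params.bend_occipital))

        def bend(mesh: TriMesh) -> TriMesh:
            width0 = np.ptp(mesh.vertices[:, 0])
            v = mesh.vertices.copy()
            y = v[:, 1]
            v[:, 0] += tf * np.maximum(y - yq_f, 0.0)
            v[:, 0] += to * np.maximum(yq_o - y, 0.0)
            return _restore_width(mesh.with_vertices(v), width0)

        left, right = bend(left), bend(right)

    if params.msp_tilt:
        R = Rotation.from_euler("z", params.msp_tilt, degrees=True).as_matrix()
        left = left.with_vertices(left.vertices @ R.T)
        right = right.with_vertices(right.vertices @ R.T)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        nl, nr = left.n_vertices, right.n_vertices
        disp = _smooth_noise(np.vstack([left.vertices, right.vertices]),
                             rng, params.noise_sd)
        left = left.with_vertices(left.vertices + disp[:nl])
        right = right.with_vertices(right.vertices + disp[nl:])

    realized = replace(params,
                       petalia_frontal=pf_target,
                       petalia_occipital=po_target,
                       delta_length=pf_target - po_target)
    meta = dict(brain.metadata)
    meta["truth"] = realized
    return replace(brain, left=left, right=right, aligned=False, metadata=meta)


# --- cohort simulation -----------------------------------------------------

def _regime_from_reference(species: str, zero_means: bool) -> dict:
    """(mean, sd) per torque parameter from the published cohort summaries."""
    table = reference.ASYMMETRY[species]
    name_map = {
        "petalia_frontal": "petalia_frontal",
        "petalia_occipital": "petalia_occipital",
        "shift_frontal": "shift_frontal",
        "shift_occipital": "shift_occipital",
        "bend_frontal": "bending_frontal",
        "bend_occipital": "bending_occipital",
        "delta_height": "delta_height",
        "delta_width": "delta_width",
    }
    out = {}
    for param, var in name_map.items():
        mean = 0.0 if zero_means else table[var]["mean"]
        out[param] = (mean, reference.asymmetry_sd(species, var))
    # length asymmetry is identically frontal - occipital petalia (the poles
    # are the length extremes), so it is not drawn independently: it emerges
    # from the petalia draws with approximately the published spread
    out["delta_length"] = (0.0, 0.0)
    return out


def _build_regimes() -> dict:
    human = _regime_from_reference("human", zero_means=False)
    chimp = _regime_from_reference("chimpanzee", zero_means=True)
    null = _regime_from_reference("human", zero_means=True)
    # chimp brain is ~0.64 of human linear size (whole-surface length ratio)
    human["global_scale"] = (1.0, 0.0)
    chimp["global_scale"] = (0.64, 0.0)
    null["global_scale"] = (1.0, 0.0)
    for regime in (human, chimp, null):
        regime["msp_tilt"] = (0.0, 1.5)   # residual registration tilt, deg
    return {"human-like": human, "chimp-like": chimp, "null": null}


#: Sampling distributions (mean, sd) per parameter for each cohort regime.
#: "human-like" and "chimp-like" follow the published cohort summaries
#: (chimp-like centred on zero: no population-level torque); "null" keeps
#: human-like spread with zero means, for type-I calibration.
REGIMES = _build_regimes()


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated cohort.

    ``overrides`` replaces individual (mean, sd) pairs of the regime;
    ``noise_sd`` is the per-vertex Gaussian segmentation jitter in mm.
    """

    n: int
    regime: str = "human-like"
    seed: int = 0
    resolution: int = 48
    noise_sd: float = 0.25
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {sorted(REGIMES)}")
        for key, (mu, sd) in self.overrides.items():
            if sd < 0:
                raise ValueError(f"negative sd for {key}")


def sample_params(spec: CohortSpec, rng: np.random.Generator,
                  seed: int = 0) -> TorqueParams:
    """Draw one subject's ground-truth parameters from the regime."""
    dist = dict(REGIMES[spec.regime])
    dist.update(spec.overrides)
    draws = {}
    for key, (mu, sd) in dist.items():
        draws[key] = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
    draws["global_scale"] = max(draws.get("global_scale", 1.0), 1e-3)
    return TorqueParams(noise_sd=spec.noise_sd, seed=seed, **draws)


def simulate_cohort(spec: CohortSpec) -> tuple[list[BrainSurface], pd.DataFrame]:
    """Simulate ``spec.n`` subjects; returns (brains, ground-truth table).

    Deterministic given ``spec.seed``: parameters are drawn from the
    regime's normal distributions, one subject at a time, and each subject
    carries its own noise seed derived from the cohort seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = make_brain(resolution=spec.resolution)
    brains, rows = [], []
    for i in range(spec.n):
        noise_seed = int(rng.integers(0, 2**31 - 1))
        params = sample_params(spec, rng, seed=noise_seed)
        subject = replace(base, subject_id=f"{spec.regime}-{i:03d}",
                          species="synthetic")
        brains.append(apply_torque(subject, params))
        rows.append({"subject_id": subject.subject_id, **params.as_dict()})
    return brains, pd.DataFrame(rows)
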