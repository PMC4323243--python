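"""Synthetic skull landmark sets, observer noise, and mesh phantoms.

Real cephalometric landmark data come from patient CBCT scans and are not
distributable, so this module generates stand-ins with exactly known ground
truth:

* a bilaterally symmetric adult skull landmark template (mirror plane
  X = 0, all horizontal-plane landmarks coplanar at Y = 0) at realistic
  anthropometric scale;
* controllable deformations — occlusal cant (degrees), lateral chin
  deviation (mm, positive = right), per-side mandibular setback (mm) —
  applied in a fixed order with their closed-form effect on every
  downstream metric recorded;
* per-landmark zero-mean Gaussian observer placement noise, deterministic
  per (seed, observer, trial);
* closed pre/post surface-mesh phantom pairs (slab or ellipsoid) whose
  regional volume difference, surface area and soft-to-hard movement ratio
  are known analytically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .geometry import Plane
from .landmarks import LandmarkSet

# ---------------------------------------------------------------------------
# Symmetric adult skull template (mm).
#
# Frame: X positive to subject's right, Y superior, Z anterior. Y = 0 is the
# common horizontal-landmark level: orbitale, porion, lateral semicircular
# canal and nasion all sit on it so that, undeformed, the five horizontal
# reference planes coincide exactly — the idealized null against which
# injected asymmetry is measured. Scale: inter-porion width 110 mm, nasion
# ~80 mm anterior of the porion axis, lower face extending ~70 mm below.

TEMPLATE_POINTS = {
    "PoR": (55.0, 0.0, -60.0),
    "PoL": (-55.0, 0.0, -60.0),
    "OrR": (32.0, 0.0, 30.0),
    "OrL": (-32.0, 0.0, 30.0),
    "LsR": (34.0, 0.0, -55.0),
    "LsL": (-34.0, 0.0, -55.0),
    "N": (0.0, 0.0, 20.0),
    "Ba": (0.0, -25.0, -45.0),
    "ANS": (0.0, -22.0, 88.0),
    "UI": (0.0, -32.0, 85.0),
    "LI": (0.0, -38.0, 83.0),
    "Pog": (0.0, -60.0, 82.0),
    "Me": (0.0, -68.0, 76.0),
    "UR3": (17.0, -30.0, 76.0),
    "UL3": (-17.0, -30.0, 76.0),
    "UR6": (29.0, -28.0, 45.0),
    "UL6": (-29.0, -28.0, 45.0),
    "LR3": (16.0, -36.0, 74.0),
    "LL3": (-16.0, -36.0, 74.0),
    "LR6": (30.0, -34.0, 44.0),
    "LL6": (-30.0, -34.0, 44.0),
}

#: landmarks rotated by the occlusal cant (paired dental cusps)
CANT_LANDMARKS = ("UR3", "UL3", "UR6", "UL6", "LR3", "LL3", "LR6", "LL6")
#: landmarks translated laterally by chin deviation
CHIN_LANDMARKS = ("Me", "Pog", "LI")
#: mandibular landmarks moved posteriorly by a setback
SETBACK_RIGHT = ("LR3", "LR6")
SETBACK_LEFT = ("LL3", "LL6")
SETBACK_MIDLINE = ("Me", "Pog", "LI")


@dataclass(frozen=True)
class SkullTemplate:
    """Canonical symmetric landmark coordinates; mirror plane X = 0."""

    points: dict = field(default_factory=lambda: dict(TEMPLATE_POINTS))

    @property
    def mirror_plane(self) -> Plane:
        return Plane(np.array([1.0, 0.0, 0.0]), 0.0)

    def molar_half_width(self, metric: str = "U6") -> float:
        pair = {"U3": "UR3", "U6": "UR6", "L3": "LR3", "L6": "LR6"}[metric]
        return abs(self.points[pair][0])

    def landmark_set(self, **meta) -> LandmarkSet:
        return LandmarkSet(points={n: np.array(p) for n, p in self.points.items()},
                           **meta)


@dataclass(frozen=True)
class DeformationSpec:
    """Asymmetry/deformity parameters injected into a template.

    chin_deviation_mm: lateral translation of Me/Pog/LI; positive = right,
    mirroring clinical chin-deviation magnitudes of roughly 4-12 mm.
    occlusal_cant_deg: rotation of the paired dental cusps about the
    anterior (Z) axis through the arch midline; positive raises the
    subject's right side.
    setback_right_mm / setback_left_mm: posterior translation of the
    mandibular dental landmarks per side (midline mandibular landmarks move
    by the mean).
    """

    chin_deviation_mm: float = 0.0
    occlusal_cant_deg: float = 0.0
    setback_right_mm: float = 0.0
    setback_left_mm: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expected values for a deformed subject."""

    spec: DeformationSpec
    midsagittal: Plane
    #: expected |d(left) - d(right)| for each bilateral metric (mm)
    bilateral: dict
    #: expected signed midline offsets (mm)
    midline_offsets: dict


def make_subject(
    template: SkullTemplate | None = None,
    spec: DeformationSpec | None = None,
    subject_id: str = "synthetic",
    session: str = "preop",
) -> tuple[LandmarkSet, GroundTruth]:
    """Deform the symmetric template and return exact ground truth.

    Deformations compose in a fixed order (they do not commute): occlusal
    cant rotation, then chin deviation, then setback. The cranial landmarks
    defining the reference planes are never moved, so the true midsagittal
    plane stays X = 0 and injected deviations map one-to-one onto the
    recovered metrics:

    * cant theta with cusp-pair half-width w  ->  U/L metric = 2 w sin|theta|
    * chin deviation d                        ->  Me/Pog/LI offset = d
    """
    template = template or SkullTemplate()
    spec = spec or DeformationSpec()
    pts = {n: np.array(p, dtype=float) for n, p in template.points.items()}

    theta = np.deg2rad(spec.occlusal_cant_deg)
    if theta != 0.0:
        # rotate dental cusps about the Z axis through the arch midline
        # (x=0) at occlusal height; positive cant lowers the right side
        y0 = float(np.mean([pts[n][1] for n in CANT_LANDMARKS]))
        c, s = np.cos(theta), np.sin(theta)
        for n in CANT_LANDMARKS:
            x, y = pts[n][0], pts[n][1] - y0
            pts[n][0] = c * x - s * y
            pts[n][1] = s * x + c * y + y0

    if spec.chin_deviation_mm != 0.0:
        for n in CHIN_LANDMARKS:
            pts[n][0] += spec.chin_deviation_mm

    if spec.setback_right_mm or spec.setback_left_mm:
        for n in SETBACK_RIGHT:
            pts[n][2] -= spec.setback_right_mm
        for n in SETBACK_LEFT:
            pts[n][2] -= spec.setback_left_mm
        mid = 0.5 * (spec.setback_right_mm + spec.setback_left_mm)
        for n in SETBACK_MIDLINE:
            pts[n][2] -= mid

    ls = LandmarkSet(points=pts, subject_id=subject_id, session=session)

    sin_t = abs(np.sin(theta))
    truth = GroundTruth(
        spec=spec,
        midsagittal=template.mirror_plane,
        bilateral={
            m: 2.0 * template.molar_half_width(m) * sin_t
            for m in ("U3", "U6", "L3", "L6")
        },
        midline_offsets={
            "ANS": 0.0,
            "UI": 0.0,
            "LI": spec.chin_deviation_mm,
            "Pog": spec.chin_deviation_mm,
            "Me": spec.chin_deviation_mm,
        },
    )
    return ls, truth


def observe(
    ls: LandmarkSet,
    sigma_mm=(0.2, 0.2, 0.2),
    observer: str = "obs1",
    trial: int = 1,
    seed: int = 0,
) -> LandmarkSet:
    """Simulated digitisation: per-axis zero-mean Gaussian placement noise.

    Deterministic per (seed, observer, trial): the RNG stream is derived
    from those values and landmarks are perturbed in sorted-name order, so
    repeated calls reproduce byte-identical coordinates.
    """
    sigma = np.broadcast_to(np.asarray(sigma_mm, dtype=float), (3,))
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    tag = zlib.crc32(f"{observer}|{ls.subject_id}|{ls.session}".encode())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), tag, int(trial)]))
    pts = {}
    for name in sorted(ls.points):
        pts[name] = ls.points[name] + rng.normal(0.0, 1.0, 3) * sigma
    return replace(ls, points=pts, observer=observer, trial=trial)


def make_cohort(
    n_subjects: int,
    seed: int = 0,
    chin_deviation_range=(0.0, 0.0),
    occlusal_cant_range=(0.0, 0.0),
    anatomy_sigma_mm: float = 0.0,
    session: str = "preop",
):
    """Cohort of deformed subjects with per-subject uniform random severity.

    Deviation sides alternate via a random sign. `anatomy_sigma_mm` adds
    per-subject, per-landmark Gaussian offsets emulating inter-individual
    anatomical variation (fixed for a subject, so shared by all of that
    subject's digitisations); with a nonzero value the closed-form
    GroundTruth metrics no longer hold exactly. Returns a list of
    (LandmarkSet, GroundTruth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 12707]))
    out = []
    for i in range(n_subjects):
        dev = rng.uniform(*chin_deviation_range) * rng.choice([-1.0, 1.0])
        cant = rng.uniform(*occlusal_cant_range) * rng.choice([-1.0, 1.0])
        spec = DeformationSpec(
            chin_deviation_mm=float(dev),
            occlusal_cant_deg=float(cant),
            seed=int(seed),
        )
        ls, truth = make_subject(
            spec=spec, subject_id=f"S{i + 1:03d}", session=session
        )
        if anatomy_sigma_mm > 0.0:
            pts = {
                n: ls.points[n] + rng.normal(0.0, anatomy_sigma_mm, 3)
                for n in sorted(ls.points)
            }
            ls = replace(ls, points=pts)
        out.append((ls, truth))
    return out


# ---------------------------------------------------------------------------
# Mesh phantoms


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic expectations for a pre/post mesh phantom pair."""

    volume_difference_mm3: float
    moved_surface_area_mm2: float
    average_movement_mm: float
    #: half-space selecting the moved face region (normal, offset)
    region_plane: Plane | None = None


def make_mesh_phantom(kind: str = "slab", **params):
    """Closed pre/post mesh pair with analytically known volume change.

    kind="slab": a cube of edge `size_mm` (default 20) whose +X face is
    offset outward by `offset_mm` (default 2). The moved-face region is the
    half-space x >= size/2; ground truth: dV = offset * size^2, moved area
    = size^2, average movement = offset.

    kind="ellipsoid": an icosphere-based ellipsoid with semi-axes `radii_mm`
    (default (12, 10, 9)) whose X semi-axis is scaled by `scale` (default
    1.05); ground truth volume change uses the exact discrete mesh volumes
    (which approach 4/3 pi abc as the sphere is refined).

    Returns (pre_mesh, post_mesh, PhantomTruth) as trimesh.Trimesh objects.
    """
    if kind == "slab":
        size = float(params.get("size_mm", 20.0))
        offset = float(params.get("offset_mm", 2.0))
        pre = trimesh.creation.box(extents=[size, size, size])
        post = trimesh.creation.box(extents=[size + offset, size, size])
        post.apply_translation([offset / 2.0, 0.0, 0.0])
        truth = PhantomTruth(
            volume_difference_mm3=offset * size * size,
            moved_surface_area_mm2=size * size,
            average_movement_mm=offset,
            region_plane=Plane(np.array([1.0, 0.0, 0.0]), size / 2.0),
        )
        return pre, post, truth
    if kind == "ellipsoid":
        radii = np.asarray(params.get("radii_mm", (12.0, 10.0, 9.0)), dtype=float)
        scale = float(params.get("scale", 1.05))
        subdiv = int(params.get("subdivisions", 4))
        unit = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
        pre = unit.copy()
        pre.apply_scale(radii)
        post = unit.copy()
        post.apply_scale(radii * np.array([scale, 1.0, 1.0]))
        truth = PhantomTruth(
            volume_difference_mm3=float(post.volume - pre.volume),
            moved_surface_area_mm2=float(pre.area),
            average_movement_mm=float(post.volume - pre.volume) / float(pre.area),
            region_plane=None,
        )
        return pre, post, truth
    raise ValueError(f"unknown phantom kind {kind!r}")


def make_tissue_phantoms(
    soft_offset_mm: float = 1.6,
    hard_offset_mm: float = 2.0,
    size_mm: float = 20.0,
):
    """Soft+hard slab phantom pairs with known soft-to-hard ratio.

    Returns ((soft_pre, soft_post), (hard_pre, hard_post), truth) where the
    true soft-to-hard average-movement ratio is soft_offset/hard_offset.
    """
    soft = make_mesh_phantom("slab", size_mm=size_mm, offset_mm=soft_offset_mm)
    hard = make_mesh_phantom("slab", size_mm=size_mm, offset_mm=hard_offset_mm)
    ratio = soft_offset_mm / hard_offset_mm
    return soft[:2], hard[:2], {"ratio": ratio, "soft": soft[2], "hard": hard[2]}
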