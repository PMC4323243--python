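"""Construction of the five horizontal reference planes and midsagittal planes.

Five landmark-oriented horizontal planes are built from the orbitale,
porion, lateral-semicircular-canal and nasion landmarks:

====== =======================================================
name   defining points
====== =======================================================
FHP_P  average porion (PoA), right orbitale, left orbitale
FHP_O  average orbitale (OrA), right porion, left porion
FHP_L  left porion, right orbitale, left orbitale
FHP_R  right porion, right orbitale, left orbitale
LSP    right and left lateral semicircular canals, nasion
====== =======================================================

From each horizontal plane a midsagittal plane is derived as the unique
plane containing nasion and basion and perpendicular to that horizontal
plane. Horizontal normals are oriented superiorly (+Y); midsagittal normals
point to the subject's right (+X), so a positive signed distance means a
landmark lies on the subject's right of the midline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError
from .geometry import Plane, plane_from_three_points, point_plane_distance
from .landmarks import LandmarkSet, require, with_derived_midpoints

HORIZONTAL_PLANES = ("FHP_P", "FHP_O", "FHP_L", "FHP_R", "LSP")
#: the four Frankfort-horizontal variants (the usual midsagittal parents)
FHP_PLANES = ("FHP_P", "FHP_O", "FHP_L", "FHP_R")

PLANE_DEFINITIONS = {
    "FHP_P": ("PoA", "OrR", "OrL"),
    "FHP_O": ("OrA", "PoR", "PoL"),
    "FHP_L": ("PoL", "OrR", "OrL"),
    "FHP_R": ("PoR", "OrR", "OrL"),
    "LSP": ("LsR", "LsL", "N"),
}

SUPERIOR = np.array([0.0, 1.0, 0.0])
SUBJECT_RIGHT = np.array([1.0, 0.0, 0.0])

# minimum angle (rad) between the basion-nasion axis and a horizontal plane
# normal before the midsagittal construction is considered degenerate
EPS_ANGLE = 1e-6


@dataclass
class ReferencePlaneSet:
    """The five horizontal planes and their derived midsagittal planes."""

    horizontal: dict = field(default_factory=dict)
    midsagittal: dict = field(default_factory=dict)  # keyed by parent plane name
    defining: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> Plane:
        if name in self.horizontal:
            return self.horizontal[name]
        return self.midsagittal[name]

    def to_json(self, path=None) -> str:
        payload = {
            "horizontal": {
                name: {
                    "normal": list(map(float, pl.normal)),
                    "offset": float(pl.offset),
                    "defined_by": list(self.defining.get(name, ())),
                }
                for name, pl in self.horizontal.items()
            },
            "midsagittal": {
                parent: {
                    "normal": list(map(float, pl.normal)),
                    "offset": float(pl.offset),
                    "defined_by": ["N", "Ba", parent],
                }
                for parent, pl in self.midsagittal.items()
            },
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def build_horizontal_planes(ls: LandmarkSet) -> ReferencePlaneSet:
    """Build FHP_P, FHP_O, FHP_L, FHP_R and LSP from a landmark set.

    Average orbitale/porion midpoints are derived internally. Normals are
    oriented superiorly.
    """
    require(ls, ("OrR", "OrL", "PoR", "PoL", "LsR", "LsL", "N"))
    full = with_derived_midpoints(ls)
    out = ReferencePlaneSet()
    for name, triple in PLANE_DEFINITIONS.items():
        plane = plane_from_three_points(
            full[triple[0]], full[triple[1]], full[triple[2]], names=triple
        )
        out.horizontal[name] = plane.oriented(SUPERIOR)
        out.defining[name] = triple
    return out


def build_midsagittal(ls: LandmarkSet, horizontal: Plane) -> Plane:
    """Midsagittal plane through nasion and basion, perpendicular to `horizontal`.

    The normal is ``horizontal.normal x (Ba - N)`` (unique up to sign),
    sign-fixed to point to the subject's right.
    """
    require(ls, ("N", "Ba"))
    axis = ls["Ba"] - ls["N"]
    axis_len = np.linalg.norm(axis)
    if axis_len == 0.0:
        raise DegenerateGeometryError("N and Ba coincide")
    normal = np.cross(horizontal.normal, axis / axis_len)
    # |normal| = sin(angle between Ba-N and the horizontal normal)
    if np.linalg.norm(normal) <= EPS_ANGLE:
        raise DegenerateGeometryError(
            "basion-nasion axis is (near-)parallel to the horizontal plane "
            "normal; midsagittal plane is undefined"
        )
    normal /= np.linalg.norm(normal)
    plane = Plane(normal, float(normal @ ls["N"]))
    return plane.oriented(SUBJECT_RIGHT)


def build_reference_planes(ls: LandmarkSet) -> ReferencePlaneSet:
    """Horizontal planes plus one derived midsagittal plane per parent."""
    planes = build_horizontal_planes(ls)
    for name, horizontal in planes.horizontal.items():
        planes.midsagittal[name] = build_midsagittal(ls, horizontal)
    return planes


def plane_pair_discrepancy(ls: LandmarkSet, a: Plane, b: Plane, probes) -> dict:
    """Per-probe absolute difference of unsigned distances to two planes (mm).

    This is the vertical-distance discrepancy used to compare reference
    planes pairwise at the dental probe points.
    """
    require(ls, probes)
    return {
        p: abs(point_plane_distance(ls[p], a) - point_plane_distance(ls[p], b))
        for p in probes
    }
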