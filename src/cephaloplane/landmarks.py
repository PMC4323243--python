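"""Controlled landmark vocabulary, validated containers, and file I/O.

Landmark sets hold named 3D points (mm) for one subject/session/observer/
trial. The vocabulary covers the cranial landmarks used to build the
horizontal reference planes (orbitale, porion, lateral semicircular canal,
nasion, basion), the midline landmarks used for symmetry assessment (ANS,
incisors, pogonion, menton), and the eight paired dental cusp points used
for occlusal-cant style bilateral comparisons.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import MissingLandmarkError, ParseError
from .geometry import RigidTransform, midpoint

# measured landmarks (files may contain exactly these)
MEASURED_LANDMARKS = (
    "OrR", "OrL", "PoR", "PoL", "LsR", "LsL",
    "N", "Ba", "ANS", "UI", "LI", "Pog", "Me",
    "UL3", "UR3", "LL3", "LR3", "UL6", "UR6", "LL6", "LR6",
)
# derived midpoints, never read from a file
DERIVED_LANDMARKS = ("OrA", "PoA")
VOCABULARY = frozenset(MEASURED_LANDMARKS) | frozenset(DERIVED_LANDMARKS)

#: left/right pairs, keyed by the left member
BILATERAL_PAIRS = {
    "OrL": "OrR", "PoL": "PoR", "LsL": "LsR",
    "UL3": "UR3", "LL3": "LR3", "UL6": "UR6", "LL6": "LR6",
}
MIDLINE_LANDMARKS = ("N", "Ba", "ANS", "UI", "LI", "Pog", "Me")

#: the landmarks that define the five horizontal planes
PLANE_LANDMARKS = ("OrR", "OrL", "PoR", "PoL", "LsR", "LsL", "N")
#: default cranial-base set for rigid pre/post superimposition
CRANIAL_BASE = ("N", "Ba", "PoR", "PoL", "LsR", "LsL")
#: dental probe points for bilateral distance comparison
DENTAL_LANDMARKS = ("UL3", "UR3", "UL6", "UR6", "LL3", "LR3", "LL6", "LR6")


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D landmark coordinates (mm) for one digitisation.

    `session` conventionally distinguishes "preop"/"postop", `observer` and
    `trial` index repeated digitisations for reliability studies.
    """

    points: dict = field(default_factory=dict)
    subject_id: str = ""
    session: str = ""
    observer: str = ""
    trial: int = 0

    def __post_init__(self):
        clean = {}
        for name, p in self.points.items():
            if name not in VOCABULARY:
                raise ParseError(f"unknown landmark name {name!r}")
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise ParseError(f"non-finite coordinates for landmark {name!r}")
            clean[name] = arr
        object.__setattr__(self, "points", clean)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    @property
    def names(self) -> tuple:
        return tuple(self.points)

    def coordinates(self, names=None) -> np.ndarray:
        """Stacked (n, 3) coordinate array in the order of `names`."""
        names = list(names) if names is not None else list(self.points)
        require(self, names)
        return np.array([self.points[n] for n in names])

    def updated(self, new_points: dict, **meta) -> "LandmarkSet":
        merged = dict(self.points)
        merged.update(new_points)
        return replace(self, points=merged, **meta)

    def transformed(self, transform: RigidTransform, **meta) -> "LandmarkSet":
        moved = {n: transform.apply(p) for n, p in self.points.items()}
        return replace(self, points=moved, **meta)

    def mirrored(self, axis: int = 0) -> "LandmarkSet":
        """Reflect through the coordinate plane `axis`=0 and swap L/R names."""
        swap = dict(BILATERAL_PAIRS)
        swap.update({v: k for k, v in BILATERAL_PAIRS.items()})
        pts = {}
        for name, p in self.points.items():
            q = p.copy()
            q[axis] = -q[axis]
            pts[swap.get(name, name)] = q
        return replace(self, points=pts)


def require(ls: LandmarkSet, names) -> None:
    """Raise MissingLandmarkError listing every absent requested landmark."""
    missing = [n for n in names if n not in ls.points]
    if missing:
        raise MissingLandmarkError(missing)


def with_derived_midpoints(ls: LandmarkSet) -> LandmarkSet:
    """Add the average orbitale (OrA) and average porion (PoA) midpoints."""
    require(ls, ("OrR", "OrL", "PoR", "PoL"))
    return ls.updated({
        "OrA": midpoint(ls["OrR"], ls["OrL"]),
        "PoA": midpoint(ls["PoR"], ls["PoL"]),
    })


def _meta_from_record(record: dict) -> dict:
    meta = {}
    for key in ("subject_id", "session", "observer"):
        if record.get(key) not in (None, ""):
            meta[key] = str(record[key])
    if record.get("trial") not in (None, ""):
        try:
            meta["trial"] = int(record["trial"])
        except (TypeError, ValueError):
            raise ParseError(f"non-integer trial {record['trial']!r}")
    return meta


def load_landmarks(path, format: str | None = None) -> LandmarkSet:
    """Read a landmark set from CSV (`name,x,y,z`) or JSON.

    The format is inferred from the file suffix unless given. Unknown names,
    duplicates and non-numeric coordinates raise ParseError with the row.
    Derived names (OrA, PoA) are rejected: they are always recomputed.
    """
    path = str(path)
    fmt = format or ("json" if path.lower().endswith(".json") else "csv")
    if fmt == "csv":
        return _load_csv(path)
    if fmt == "json":
        return _load_json(path)
    raise ParseError(f"unsupported landmark format {fmt!r}", path=path)


def _validate_point(name, xyz, row, path, seen):
    if name in DERIVED_LANDMARKS:
        raise ParseError(
            f"derived landmark {name!r} may not be supplied", row=row, path=path
        )
    if name not in VOCABULARY:
        raise ParseError(f"unknown landmark name {name!r}", row=row, path=path)
    if name in seen:
        raise ParseError(f"duplicate landmark {name!r}", row=row, path=path)
    try:
        point = [float(v) for v in xyz]
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric coordinate for {name!r}: {tuple(xyz)!r}",
            row=row, path=path,
        )
    if not all(np.isfinite(point)):
        raise ParseError(f"non-finite coordinate for {name!r}", row=row, path=path)
    seen[name] = np.array(point)


def _load_csv(path: str) -> LandmarkSet:
    meta: dict = {}
    seen: dict = {}
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise ParseError("empty landmark file", path=path)
    header = [h.strip() for h in rows[0]]
    expected = ["name", "x", "y", "z"]
    if [h.lower() for h in header[:4]] != expected:
        raise ParseError(
            f"expected header name,x,y,z, got {','.join(header)}", row=1, path=path
        )
    extra_cols = [h.lower() for h in header[4:]]
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < 4:
            raise ParseError("row has fewer than 4 fields", row=i, path=path)
        name = row[0].strip()
        _validate_point(name, row[1:4], i, path, seen)
        for col, value in zip(extra_cols, row[4:]):
            rec = _meta_from_record({col: value.strip()})
            for k, v in rec.items():
                if k in meta and meta[k] != v:
                    raise ParseError(
                        f"conflicting {k} metadata {v!r}", row=i, path=path
                    )
            meta.update(rec)
    return LandmarkSet(points=seen, **meta)


def _load_json(path: str) -> LandmarkSet:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    pts = data.get("landmarks", data if isinstance(data, dict) else None)
    if not isinstance(pts, dict):
        raise ParseError("JSON landmark file must map names to [x, y, z]", path=path)
    seen: dict = {}
    for name, xyz in pts.items():
        if name in ("subject_id", "session", "observer", "trial"):
            continue
        if not isinstance(xyz, (list, tuple)) or len(xyz) != 3:
            raise ParseError(f"landmark {name!r} is not a 3-vector", path=path)
        _validate_point(name, xyz, None, path, seen)
    meta = _meta_from_record(data if "landmarks" in data else {})
    return LandmarkSet(points=seen, **meta)


def save_landmarks(ls: LandmarkSet, path, format: str | None = None) -> None:
    """Write a landmark set in the same dialect `load_landmarks` reads.

    Derived midpoints are not written; they are recomputed on load.
    """
    path = str(path)
    fmt = format or ("json" if path.lower().endswith(".json") else "csv")
    stored = {n: p for n, p in ls.points.items() if n not in DERIVED_LANDMARKS}
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["name", "x", "y", "z", "subject_id", "session", "observer", "trial"]
            )
            for name in sorted(stored):
                p = stored[name]
                writer.writerow(
                    [name, repr(float(p[0])), repr(float(p[1])), repr(float(p[2])),
                     ls.subject_id, ls.session, ls.observer, ls.trial]
                )
    elif fmt == "json":
        payload = {
            "subject_id": ls.subject_id,
            "session": ls.session,
            "observer": ls.observer,
            "trial": ls.trial,
            "landmarks": {n: list(map(float, stored[n])) for n in sorted(stored)},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ParseError(f"unsupported landmark format {fmt!r}", path=path)
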