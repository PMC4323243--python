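"""Bilateral distance asymmetry metrics and signed midline offsets.

Two complementary quantifications of facial asymmetry:

* **Bilateral distance differences** (U3, U6, L3, L6): for each horizontal
  reference plane, the absolute difference between the unsigned distances
  of a left/right dental cusp pair to the plane, e.g.
  ``U3 = | d(UL3) - d(UR3) |``. Zero for a perfectly level occlusion.

* **Signed midline offsets**: the signed distance of the midline landmarks
  ANS, UI, LI, Pog, Me to each FHP-derived midsagittal plane; positive
  values lie on the subject's right of the midline. Chin deviation is read
  directly from the menton (Me) offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .geometry import point_plane_distance
from .landmarks import LandmarkSet, require
from .reference_planes import FHP_PLANES, ReferencePlaneSet, build_midsagittal

#: bilateral metric -> (left landmark, right landmark)
METRIC_PAIRS = {
    "U3": ("UL3", "UR3"),
    "U6": ("UL6", "UR6"),
    "L3": ("LL3", "LR3"),
    "L6": ("LL6", "LR6"),
}
MIDLINE_PROBES = ("ANS", "UI", "LI", "Pog", "Me")

#: clinical chin-deviation threshold for calling a face asymmetric (mm)
ASYMMETRY_THRESHOLD_MM = 4.0


@dataclass
class AsymmetryReport:
    """Per-plane bilateral metrics and signed midline offsets for one subject."""

    subject_id: str = ""
    session: str = ""
    #: plane name -> {metric -> mm}
    bilateral: dict = field(default_factory=dict)
    #: parent plane name -> {midline landmark -> signed mm}
    midline: dict = field(default_factory=dict)

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for plane, metrics in self.bilateral.items():
            for metric, value in metrics.items():
                rows.append((self.subject_id, self.session, plane, metric, value))
        for plane, offsets in self.midline.items():
            for lm, value in offsets.items():
                rows.append(
                    (self.subject_id, self.session, plane, f"offset_{lm}", value)
                )
        return pd.DataFrame(
            rows, columns=["subject", "session", "plane", "metric", "value"]
        )


def bilateral_differences(
    ls: LandmarkSet,
    planes: ReferencePlaneSet,
    signed: bool = False,
) -> AsymmetryReport:
    """U3/U6/L3/L6 per horizontal plane.

    With ``signed=True`` the raw difference d(left) - d(right) is returned
    instead of its absolute value (useful to see which side is longer; the
    standard report uses absolute differences).
    """
    needed = [lm for pair in METRIC_PAIRS.values() for lm in pair]
    require(ls, needed)
    report = AsymmetryReport(subject_id=ls.subject_id, session=ls.session)
    for plane_name, plane in planes.horizontal.items():
        metrics = {}
        for metric, (left, right) in METRIC_PAIRS.items():
            diff = point_plane_distance(ls[left], plane) - point_plane_distance(
                ls[right], plane
            )
            metrics[metric] = diff if signed else abs(diff)
        report.bilateral[plane_name] = metrics
    return report


def midline_offsets(
    ls: LandmarkSet,
    planes: ReferencePlaneSet,
    parents=FHP_PLANES,
    probes=MIDLINE_PROBES,
) -> AsymmetryReport:
    """Signed distances of midline landmarks to each derived midsagittal plane.

    Positive = the landmark lies to the subject's right of the midsagittal
    plane. Midsagittal planes missing from `planes` are derived on the fly.
    By default only the four FHP-derived planes are reported; pass
    ``parents=HORIZONTAL_PLANES`` to include the LSP-derived plane too.
    """
    require(ls, tuple(probes) + ("N", "Ba"))
    report = AsymmetryReport(subject_id=ls.subject_id, session=ls.session)
    for parent in parents:
        ms = planes.midsagittal.get(parent)
        if ms is None:
            ms = build_midsagittal(ls, planes.horizontal[parent])
        report.midline[parent] = {
            p: point_plane_distance(ls[p], ms, signed=True) for p in probes
        }
    return report


def full_report(ls: LandmarkSet, planes: ReferencePlaneSet, **kwargs) -> AsymmetryReport:
    """Bilateral metrics and midline offsets combined in one report."""
    rep = bilateral_differences(ls, planes)
    rep.midline = midline_offsets(ls, planes, **kwargs).midline
    return rep


def is_asymmetric(
    report: AsymmetryReport,
    plane: str = "FHP_P",
    threshold_mm: float = ASYMMETRY_THRESHOLD_MM,
) -> bool:
    """Clinical asymmetry call: |Me midline offset| beyond the 4 mm threshold."""
    try:
        me = report.midline[plane]["Me"]
    except KeyError:
        raise UsageError(
            f"report has no Me offset for plane {plane!r}; "
            "run midline_offsets first"
        ) from None
    return abs(me) > threshold_mm


@dataclass
class CohortSummary:
    """Mean +/- SD of each (plane, metric) over a cohort of subjects."""

    label: str
    n: int
    table: pd.DataFrame  # index (plane, metric), columns mean/sd

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide table: one row per plane, 'mean+/-sd' strings per metric."""
        txt = self.table.apply(
            lambda r: f"{r['mean']:.2f}±{r['sd']:.2f}", axis=1
        )
        return txt.unstack("metric")


def summarize_cohort(reports, label: str = "") -> CohortSummary:
    """Sample mean and SD (n-1 denominator) per (plane, metric) over subjects."""
    reports = list(reports)
    if not reports:
        raise UsageError("summarize_cohort needs at least one report")
    frames = [r.to_tidy_frame() for r in reports]
    tidy = pd.concat(frames, ignore_index=True)
    planes = set(map(tuple, (sorted(f["plane"].unique()) for f in frames)))
    if len(planes) != 1:
        raise UsageError("all reports must cover the same plane set")
    grouped = tidy.groupby(["plane", "metric"])["value"]
    table = pd.DataFrame({"mean": grouped.mean(), "sd": grouped.std(ddof=1)})
    table["sd"] = table["sd"].fillna(0.0)
    table.index = table.index.set_names(["plane", "metric"])
    return CohortSummary(label=label, n=len(reports), table=table)


def metric_matrix(reports, metric: str, planes) -> np.ndarray:
    """(n subjects x k planes) matrix of one metric, for rank-based tests."""
    rows = []
    for r in reports:
        if metric.startswith("offset_"):
            lm = metric[len("offset_"):]
            rows.append([r.midline[p][lm] for p in planes])
        else:
            rows.append([r.bilateral[p][metric] for p in planes])
    return np.asarray(rows, dtype=float)
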