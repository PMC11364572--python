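"""Cobb angle computation from fitted endplate planes.

Angle conventions
-----------------
The *coronal angle* of an endplate plane is the lateral tilt of its normal:
``asin(n_R)`` for the cranially sign-normalized unit normal ``n`` in the
canonical (S, A, R) frame.  Positive angles lean toward the patient's right.
When the spine carries no sagittal tilt this equals the tilt of the endplate
line seen on an AP radiograph (the projection of the plane onto the coronal
plane); unlike the raw projected angle, it is *exactly* invariant under
global rotations about the LR axis, so lumbar lordosis or a tilted
acquisition cannot leak into the coronal measurement.  The *sagittal angle*
is the mirror definition, ``asin(n_A)``.

Cobb enumeration
----------------
Each disc contributes two endplate angles: its lower half is parallel to the
superior endplate of the vertebra below, its upper half to the inferior
endplate of the vertebra above.  Every cranio-caudally ordered pair of discs
(a strictly above b) yields a candidate Cobb angle
``|angle_lower(a) - angle_upper(b)|`` between the superior endplate of the
vertebra below a (top level) and the inferior endplate of the vertebra above
b (bottom level).  The Cobb angle is the maximum over all candidates — the
two most tilted endplates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .disc_geometry import DiscPlanes, Plane
from .errors import (
    NoMeasurementError,
    OrderingError,
    UnavailableLevelError,
    UndefinedAngleError,
)
from .mask_io import LabelScheme, QCReport

__all__ = [
    "PlaneKind",
    "DiscAngles",
    "EndplateAngleTable",
    "CobbMeasurement",
    "coronal_angle",
    "sagittal_angle",
    "build_angle_table",
    "candidate_angles",
    "max_cobb",
    "cobb_at_levels",
    "measurement_report",
]

PlaneKind = Literal["coronal", "sagittal"]

_REPORT_SCHEMA = "cobbmri-measurement/1"


def coronal_angle(plane: Plane) -> float:
    """Signed coronal endplate tilt in degrees, range (-90, 90].

    Positive for normals leaning into the patient-right half-space.  Raises
    :class:`UndefinedAngleError` for a (non-anatomical) near-pure-AP normal,
    for which the endplate has no footprint in the coronal view.
    """
    n = plane.n
    if math.hypot(n[0], n[2]) < 1e-6:
        raise UndefinedAngleError("normal is (near-)parallel to the AP axis")
    return math.degrees(math.asin(max(-1.0, min(1.0, n[2]))))


def sagittal_angle(plane: Plane) -> float:
    """Signed sagittal endplate tilt in degrees; positive leans anteriorly."""
    n = plane.n
    if math.hypot(n[0], n[1]) < 1e-6:
        raise UndefinedAngleError("normal is (near-)parallel to the LR axis")
    return math.degrees(math.asin(max(-1.0, min(1.0, n[1]))))


@dataclass(frozen=True)
class DiscAngles:
    """Projected endplate angles of one disc.

    The upper half corresponds to the inferior endplate of ``vertebra_above``,
    the lower half to the superior endplate of ``vertebra_below``.
    """

    level: str
    vertebra_above: str
    vertebra_below: str
    upper_coronal: float
    lower_coronal: float
    upper_sagittal: float
    lower_sagittal: float
    upper_centroid: tuple[float, float, float]
    lower_centroid: tuple[float, float, float]

    def angle(self, half: Literal["upper", "lower"], kind: PlaneKind) -> float:
        return getattr(self, f"{half}_{kind}")


@dataclass
class EndplateAngleTable:
    """Per-disc endplate angles, ordered cranial -> caudal."""

    discs: list[DiscAngles]
    scheme: LabelScheme

    def __post_init__(self) -> None:
        for rec in self.discs:
            for kind in ("coronal", "sagittal"):
                for half in ("upper", "lower"):
                    a = rec.angle(half, kind)  # type: ignore[arg-type]
                    if not (-90.0 < a <= 90.0):
                        raise ValueError(f"angle {a} out of (-90, 90] for disc {rec.level}")

    def disc_index(self, level: str) -> int:
        for i, rec in enumerate(self.discs):
            if rec.level == level:
                return i
        raise UnavailableLevelError(f"disc {level!r} not in table", levels=[level])

    def superior_endplate(self, vertebra: str) -> DiscAngles:
        """The disc record carrying the superior endplate of ``vertebra``."""
        for rec in self.discs:
            if rec.vertebra_below == vertebra:
                return rec
        raise UnavailableLevelError(
            f"superior endplate of {vertebra!r} unavailable (no disc above it)",
            levels=[vertebra],
        )

    def inferior_endplate(self, vertebra: str) -> DiscAngles:
        for rec in self.discs:
            if rec.vertebra_above == vertebra:
                return rec
        raise UnavailableLevelError(
            f"inferior endplate of {vertebra!r} unavailable (no disc below it)",
            levels=[vertebra],
        )


@dataclass(frozen=True)
class CobbMeasurement:
    """One candidate (or the final) Cobb angle.

    ``top_source``/``bottom_source`` name the disc half each endplate angle
    came from, e.g. ``("L1-L2", "lower")``.
    """

    angle: float
    top_vertebra: str
    bottom_vertebra: str
    top_source: tuple[str, str]
    bottom_source: tuple[str, str]
    plane_kind: PlaneKind = "coronal"

    def __post_init__(self) -> None:
        if self.angle < 0:
            raise ValueError("Cobb angle must be non-negative")

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle,
            "top_vertebra": self.top_vertebra,
            "bottom_vertebra": self.bottom_vertebra,
            "top_source": list(self.top_source),
            "bottom_source": list(self.bottom_source),
            "plane_kind": self.plane_kind,
        }


def build_angle_table(discs: list[DiscPlanes], scheme: LabelScheme) -> EndplateAngleTable:
    """Project each disc's half-planes and order the records cranio-caudally.

    Ordering is by mid-plane centroid SI coordinate (most superior first) and
    must agree with the scheme's disc order; discs whose SI extents interleave
    raise :class:`OrderingError`.
    """
    if not discs:
        raise OrderingError("need at least one disc")
    ordered = sorted(discs, key=lambda d: -d.mid_plane.c[0])
    scheme_order = [d.name for d in scheme.discs]
    try:
        positions = [scheme_order.index(d.level) for d in ordered]
    except ValueError as exc:
        raise OrderingError(f"disc level not in scheme: {exc}") from exc
    if positions != sorted(positions):
        raise OrderingError("cranio-caudal centroid order contradicts the scheme order")
    for upper, lower in zip(ordered, ordered[1:]):
        if upper.lower_plane.c[0] < lower.upper_plane.c[0]:
            raise OrderingError(
                f"discs {upper.level!r} and {lower.level!r} have interleaved SI extents"
            )
    records = []
    for dp in ordered:
        disc = scheme.disc_by_name(dp.level)
        records.append(
            DiscAngles(
                level=dp.level,
                vertebra_above=disc.above,
                vertebra_below=disc.below,
                upper_coronal=coronal_angle(dp.upper_plane),
                lower_coronal=coronal_angle(dp.lower_plane),
                upper_sagittal=sagittal_angle(dp.upper_plane),
                lower_sagittal=sagittal_angle(dp.lower_plane),
                upper_centroid=tuple(dp.upper_plane.c),
                lower_centroid=tuple(dp.lower_plane.c),
            )
        )
    return EndplateAngleTable(discs=records, scheme=scheme)


def candidate_angles(
    table: EndplateAngleTable,
    plane_kind: PlaneKind = "coronal",
    min_span: int = 1,
) -> list[CobbMeasurement]:
    """All candidate Cobb angles over ordered disc pairs.

    ``min_span`` is the minimum number of vertebrae between (and including)
    the top and bottom level; the default 1 admits single-vertebra candidates
    from adjacent discs.
    """
    if not table.discs:
        raise NoMeasurementError("empty angle table")
    out: list[CobbMeasurement] = []
    for i, a in enumerate(table.discs):
        for b in table.discs[i + 1:]:
            top = a.vertebra_below
            bottom = b.vertebra_above
            span = table.scheme.vertebra_index(bottom) - table.scheme.vertebra_index(top) + 1
            if span < min_span:
                continue
            theta = abs(a.angle("lower", plane_kind) - b.angle("upper", plane_kind))
            out.append(
                CobbMeasurement(
                    angle=theta,
                    top_vertebra=top,
                    bottom_vertebra=bottom,
                    top_source=(a.level, "lower"),
                    bottom_source=(b.level, "upper"),
                    plane_kind=plane_kind,
                )
            )
    return out


def max_cobb(
    candidates: list[CobbMeasurement], scheme: LabelScheme | None = None
) -> CobbMeasurement:
    """The maximal candidate.

    Ties (exactly equal angles) are broken deterministically: first by larger
    vertebral span, then by the more cranial top level.  ``scheme`` supplies
    the level ordering; without it, ties fall back to list order.
    """
    if not candidates:
        raise NoMeasurementError("no Cobb candidates")

    if scheme is not None:
        def key(m: CobbMeasurement):
            ti = scheme.vertebra_index(m.top_vertebra)
            bi = scheme.vertebra_index(m.bottom_vertebra)
            return (m.angle, bi - ti, -ti)
    else:
        def key(m: CobbMeasurement):
            return (m.angle,)

    best = candidates[0]
    for m in candidates[1:]:
        if key(m) > key(best):
            best = m
    return best


def cobb_at_levels(
    table: EndplateAngleTable,
    top: str,
    bottom: str,
    plane_kind: PlaneKind = "coronal",
) -> CobbMeasurement:
    """Cobb angle between the superior endplate of ``top`` and the inferior
    endplate of ``bottom`` — the reader-chosen-levels variant."""
    if table.scheme.vertebra_index(top) > table.scheme.vertebra_index(bottom):
        raise ValueError(f"top level {top!r} must be cranial to (or equal) {bottom!r}")
    a = table.superior_endplate(top)
    b = table.inferior_endplate(bottom)
    theta = abs(a.angle("lower", plane_kind) - b.angle("upper", plane_kind))
    return CobbMeasurement(
        angle=theta,
        top_vertebra=top,
        bottom_vertebra=bottom,
        top_source=(a.level, "lower"),
        bottom_source=(b.level, "upper"),
        plane_kind=plane_kind,
    )


def measurement_report(
    volume_id: str,
    table: EndplateAngleTable,
    candidates: list[CobbMeasurement],
    best: CobbMeasurement,
    qc: QCReport | None = None,
    out: str | Path | None = None,
) -> dict:
    """Machine-readable measurement report (stable key names, versioned)."""
    doc = {
        "schema": _REPORT_SCHEMA,
        "volume_id": volume_id,
        "angle_table": [
            {
                "disc": r.level,
                "vertebra_above": r.vertebra_above,
                "vertebra_below": r.vertebra_below,
                "upper_coronal_deg": r.upper_coronal,
                "lower_coronal_deg": r.lower_coronal,
                "upper_sagittal_deg": r.upper_sagittal,
                "lower_sagittal_deg": r.lower_sagittal,
            }
            for r in table.discs
        ],
        "candidates": [m.to_dict() for m in candidates],
        "max_cobb": best.to_dict(),
        "qc": qc.to_dict() if qc is not None else None,
    }
    if out is not None:
        Path(out).write_text(json.dumps(doc, indent=2))
    return doc
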