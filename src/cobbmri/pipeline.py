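"""End-to-end measurement convenience: label volume -> Cobb measurement."""

from __future__ import annotations

from dataclasses import dataclass

from . import cobb_core, disc_geometry, mask_io
from .cobb_core import CobbMeasurement, EndplateAngleTable, PlaneKind
from .disc_geometry import GeometryConfig
from .errors import EmptyStructureError
from .mask_io import LabeledVolume, LabelScheme, QCConfig, QCReport


@dataclass
class MeasurementResult:
    table: EndplateAngleTable
    candidates: list[CobbMeasurement]
    max_cobb: CobbMeasurement
    qc: QCReport


def measure_volume(
    volume: LabeledVolume,
    scheme: LabelScheme,
    plane_kind: PlaneKind = "coronal",
    min_span: int = 1,
    geometry: GeometryConfig | None = None,
    qc_config: QCConfig | None = None,
) -> MeasurementResult:
    """Run QC and the full Cobb pipeline on a canonical labeled volume.

    Discs absent from the volume are skipped (and show up in the QC report);
    measurement proceeds on whatever discs are present.
    """
    qc = mask_io.qc_segmentation(volume, scheme, qc_config)
    geometry = geometry or GeometryConfig()
    planes = []
    for disc in scheme.discs:
        try:
            mask, spacing = mask_io.extract_structure(volume, disc.value)
        except EmptyStructureError:
            continue
        planes.append(disc_geometry.disc_planes(mask, spacing, geometry, level=disc.name))
    table = cobb_core.build_angle_table(planes, scheme)
    candidates = cobb_core.candidate_angles(table, plane_kind=plane_kind, min_span=min_span)
    best = cobb_core.max_cobb(candidates, scheme)
    return MeasurementResult(table=table, candidates=candidates, max_cobb=best, qc=qc)
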