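"""Coronal projection images — the AP-radiograph surrogate.

Collapsing the 3D vertebra masks along the AP axis with thickness weighting
produces a 2D image whose graded intensities mimic radiographic attenuation;
this is the image readers annotate in lieu of a radiograph.  Rows run
cranial -> caudal (cranial at the top), columns left -> right.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cobb_core import CobbMeasurement, EndplateAngleTable  # noqa: E402
from .mask_io import LabeledVolume  # noqa: E402

__all__ = ["ProjectionImage", "OverlayLine", "coronal_projection", "render_measurement"]


@dataclass
class ProjectionImage:
    """2D coronal projection; ``pixels[i, j]`` is the summed AP thickness (mm)
    of the selected structures at SI row i (cranial first) and LR column j."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]  # (SI, LR) mm
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("projection must be 2D")
        if self.pixels.min() < 0:
            raise ValueError("projection values must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    def mm_to_pixel(self, s_mm: float, r_mm: float) -> tuple[float, float]:
        """Canonical (S, R) mm coordinates -> (row, col) pixel coordinates."""
        row = (self.n_rows - 1) - s_mm / self.pixel_spacing[0]
        col = r_mm / self.pixel_spacing[1]
        return row, col


def coronal_projection(
    volume: LabeledVolume, labels: Iterable[int], provenance: str = ""
) -> ProjectionImage:
    """Thickness-weighted occupancy projection of the selected labels.

    Each pixel sums, along the AP axis, the AP voxel size over voxels whose
    label is in ``labels``; the result is additive over disjoint label sets
    and commutes with LR mirroring.
    """
    label_set = set(int(x) for x in labels)
    if not label_set:
        raise ValueError("empty label selection")
    occ = np.isin(volume.labels, sorted(label_set))
    proj = occ.sum(axis=1) * volume.spacing[1]     # (S, R), mm of tissue
    pixels = proj[::-1]                            # cranial at row 0
    return ProjectionImage(
        pixels=pixels,
        pixel_spacing=(volume.spacing[0], volume.spacing[2]),
        provenance=provenance,
    )


@dataclass(frozen=True)
class OverlayLine:
    """One rendered endplate line, for inspection and testing."""

    disc: str
    half: str
    p0: tuple[float, float]  # (col, row) pixel coordinates
    p1: tuple[float, float]
    highlighted: bool


def render_measurement(
    image: ProjectionImage,
    table: EndplateAngleTable,
    measurement: CobbMeasurement,
    out: str | Path,
    half_length_mm: float = 30.0,
) -> list[OverlayLine]:
    """Write a PNG of the projection with one line per fitted endplate plane.

    Each line passes through the plane centroid's (LR, SI) position at the
    plane's coronal tilt; the pair realizing ``measurement`` is highlighted.
    Returns the drawn line segments in pixel coordinates.
    """
    sp_si, sp_lr = image.pixel_spacing
    lines: list[OverlayLine] = []
    for rec in table.discs:
        for half in ("upper", "lower"):
            angle = rec.angle(half, measurement.plane_kind)  # type: ignore[arg-type]
            centroid = rec.upper_centroid if half == "upper" else rec.lower_centroid
            row_c, col_c = image.mm_to_pixel(centroid[0], centroid[2])
            # physical slope ds/dr = tan(angle); pixel rows grow caudally
            dr = half_length_mm
            ds = np.tan(np.radians(angle)) * dr
            p0 = (col_c - dr / sp_lr, row_c + ds / sp_si)
            p1 = (col_c + dr / sp_lr, row_c - ds / sp_si)
            highlighted = (rec.level, half) in (measurement.top_source, measurement.bottom_source)
            lines.append(OverlayLine(rec.level, half, p0, p1, highlighted))

    fig, ax = plt.subplots(figsize=(6, 6 * image.pixels.shape[0] * sp_si
                                    / max(image.pixels.shape[1] * sp_lr, 1e-6)))
    ax.imshow(image.pixels, cmap="gray", interpolation="nearest",
              aspect=sp_si / sp_lr)
    for ln in lines:
        ax.plot([ln.p0[0], ln.p1[0]], [ln.p0[1], ln.p1[1]],
                color="red" if ln.highlighted else "white",
                linewidth=1.8 if ln.highlighted else 0.8)
    ax.set_title(
        f"Cobb {measurement.angle:.1f}\N{DEGREE SIGN} "
        f"({measurement.top_vertebra}\N{EN DASH}{measurement.bottom_vertebra}, "
        f"{measurement.plane_kind})"
    )
    ax.set_xlim(-0.5, image.pixels.shape[1] - 0.5)
    ax.set_ylim(image.pixels.shape[0] - 0.5, -0.5)
    ax.axis("off")
    try:
        fig.savefig(str(out), dpi=150, bbox_inches="tight")
    except OSError as exc:
        raise OSError(f"cannot write overlay image to {out}: {exc}") from exc
    finally:
        plt.close(fig)
    return lines
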