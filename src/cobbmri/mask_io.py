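"""Reading, writing and quality control of labeled segmentation volumes.

A labeled volume assigns one integer label per anatomical structure
(vertebra, intervertebral disc), 0 being background — the output contract
of 3D spine segmentation models.  On load every volume is brought into a
single canonical frame so that downstream geometry never has to think
about acquisition orientation:

    axis 0: inferior  -> superior   (S)
    axis 1: posterior -> anterior   (A)
    axis 2: left      -> right      (R)

Spacing is carried per canonical axis in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml
from scipy import ndimage

from .errors import (
    EmptyStructureError,
    FormatError,
    OrientationError,
    SchemeError,
    VolumeReadError,
)

__all__ = [
    "LabeledVolume",
    "LabelScheme",
    "VertebraLabel",
    "DiscLabel",
    "QCConfig",
    "QCReport",
    "load_labeled_volume",
    "save_labeled_volume",
    "extract_structure",
    "qc_segmentation",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class LabeledVolume:
    """3D integer label array in the canonical (S, A, R) frame.

    Parameters
    ----------
    labels
        Non-negative integer array, axis order (S, A, R); 0 is background.
    spacing
        Voxel size in mm per canonical axis (S, A, R).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"labels must be integer, got {self.labels.dtype}")
        if self.labels.min() < 0:
            raise FormatError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> set[int]:
        return set(np.unique(self.labels).tolist()) - {0}


@dataclass(frozen=True)
class VertebraLabel:
    value: int
    name: str


@dataclass(frozen=True)
class DiscLabel:
    value: int
    name: str
    above: str  # vertebra immediately cranial
    below: str  # vertebra immediately caudal


@dataclass
class LabelScheme:
    """Maps label values to named structures in cranio-caudal order.

    ``vertebrae`` and ``discs`` are ordered cranial -> caudal; disc *i* must
    sit between consecutive vertebrae *i* and *i+1*.  ``ignore`` lists label
    values present in the volume that play no role in measurement (spinal
    canal, partially imaged structures at the field-of-view edge, ...).
    """

    vertebrae: list[VertebraLabel]
    discs: list[DiscLabel]
    ignore: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        values = [v.value for v in self.vertebrae] + [d.value for d in self.discs]
        values += list(self.ignore)
        if len(values) != len(set(values)):
            raise SchemeError("label values must be unique across the scheme")
        names = [v.name for v in self.vertebrae]
        if len(names) != len(set(names)):
            raise SchemeError("vertebra names must be unique")
        if len(self.discs) != max(len(self.vertebrae) - 1, 0):
            raise SchemeError(
                f"{len(self.vertebrae)} vertebrae require {len(self.vertebrae) - 1} discs, "
                f"got {len(self.discs)}"
            )
        for i, disc in enumerate(self.discs):
            if disc.above != names[i] or disc.below != names[i + 1]:
                raise SchemeError(
                    f"disc {disc.name!r} must lie between {names[i]!r} and {names[i + 1]!r}"
                )

    # -- lookups ----------------------------------------------------------- #

    def vertebra_names(self) -> list[str]:
        return [v.name for v in self.vertebrae]

    def vertebra_index(self, name: str) -> int:
        """Cranio-caudal ordinal (0 = most cranial)."""
        try:
            return self.vertebra_names().index(name)
        except ValueError:
            raise SchemeError(f"unknown vertebra {name!r}") from None

    def vertebra_value(self, name: str) -> int:
        return self.vertebrae[self.vertebra_index(name)].value

    def disc_by_name(self, name: str) -> DiscLabel:
        for d in self.discs:
            if d.name == name:
                return d
        raise SchemeError(f"unknown disc {name!r}")

    def disc_above(self, vertebra: str) -> DiscLabel | None:
        """The disc whose lower surface is the superior endplate of ``vertebra``."""
        for d in self.discs:
            if d.below == vertebra:
                return d
        return None

    def disc_below(self, vertebra: str) -> DiscLabel | None:
        for d in self.discs:
            if d.above == vertebra:
                return d
        return None

    # -- construction / serialization -------------------------------------- #

    @classmethod
    def spider_like(cls, names: list[str] | None = None) -> "LabelScheme":
        """Default scheme mimicking the SPIDER mask convention.

        Vertebrae are numbered caudal -> cranial starting at 1 for the most
        caudal level; the disc between two vertebrae carries the label of the
        vertebra above it offset by 200.
        """
        names = names if names is not None else ["L1", "L2", "L3", "L4", "L5"]
        n = len(names)
        verts = [VertebraLabel(value=n - i, name=nm) for i, nm in enumerate(names)]
        discs = [
            DiscLabel(
                value=200 + verts[i].value,
                name=f"{names[i]}-{names[i + 1]}",
                above=names[i],
                below=names[i + 1],
            )
            for i in range(n - 1)
        ]
        return cls(vertebrae=verts, discs=discs)

    @classmethod
    def default(cls) -> "LabelScheme":
        return cls.spider_like()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        verts = [VertebraLabel(int(v["value"]), str(v["name"])) for v in doc["vertebrae"]]
        discs = [
            DiscLabel(int(d["value"]), str(d["name"]), str(d["above"]), str(d["below"]))
            for d in doc.get("discs", [])
        ]
        ignore = {int(x) for x in doc.get("ignore", [])}
        return cls(vertebrae=verts, discs=discs, ignore=ignore)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "vertebrae": [{"value": v.value, "name": v.name} for v in self.vertebrae],
            "discs": [
                {"value": d.value, "name": d.name, "above": d.above, "below": d.below}
                for d in self.discs
            ],
            "ignore": sorted(self.ignore),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class QCConfig:
    """Thresholds for the segmentation shape heuristics."""

    min_component_voxels: int = 100   # fragments smaller than this are noise, not extra discs
    min_coverage_fraction: float = 0.6  # disc footprint / adjacent vertebra footprint


@dataclass
class QCReport:
    """Automated screen for segmentation errors that would corrupt the angle
    measurement: missing discs, fragmented discs, and discs collapsed to a
    fraction of the endplate."""

    missing_discs: list[str] = field(default_factory=list)
    extra_components: dict[str, int] = field(default_factory=dict)
    shape_flags: dict[str, list[str]] = field(default_factory=dict)

    @property
    def disc_count_ok(self) -> bool:
        return not self.missing_discs and not any(self.extra_components.values())

    @property
    def passed(self) -> bool:
        return self.disc_count_ok and not any(self.shape_flags.values())

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "disc_count_ok": self.disc_count_ok,
            "missing_discs": list(self.missing_discs),
            "extra_components": dict(self.extra_components),
            "shape_flags": {k: list(v) for k, v in self.shape_flags.items()},
        }


# --------------------------------------------------------------------------- #
# orientation handling
# --------------------------------------------------------------------------- #

# ITK physical space is LPS: +x = left, +y = posterior, +z = superior.
# Canonical axes expressed in LPS: S = +z, A = -y, R = -x.
_LPS_AXIS_TO_CANONICAL = {
    2: (0, +1),  # z dominant: canonical axis 0, +z is superior (no flip)
    1: (1, -1),  # y dominant: canonical axis 1, +y is posterior (flip)
    0: (2, -1),  # x dominant: canonical axis 2, +x is left (flip)
}


def _canonical_layout(direction: np.ndarray, path: str) -> list[tuple[int, bool]]:
    """For each canonical axis, the (image axis, flip) that realizes it.

    ``direction`` is the 3x3 ITK direction matrix (column j = unit direction
    of image axis j in LPS coordinates).
    """
    if not np.all(np.isfinite(direction)):
        raise OrientationError(f"non-finite orientation metadata in {path}")
    assignment: dict[int, tuple[int, bool]] = {}
    for j in range(3):
        col = direction[:, j]
        k = int(np.argmax(np.abs(col)))
        if abs(col[k]) <= np.sqrt(0.5):
            raise OrientationError(
                f"ambiguous (strongly oblique) orientation for image axis {j} in {path}"
            )
        canon, pos_sign = _LPS_AXIS_TO_CANONICAL[k]
        flip = (np.sign(col[k]) * pos_sign) < 0
        if canon in assignment:
            raise OrientationError(f"orientation maps two image axes to one anatomical axis in {path}")
        assignment[canon] = (j, bool(flip))
    return [assignment[c] for c in range(3)]


def load_labeled_volume(path: str | Path, scheme: LabelScheme | None = None) -> LabeledVolume:
    """Read a NIfTI or MetaImage label volume and canonicalize its orientation.

    The label values are returned unchanged; only the axis order/direction is
    normalized.  ``scheme`` is accepted for interface symmetry and future
    validation but labels outside the scheme are kept (they may be in
    ``scheme.ignore``).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeReadError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError for most failures
        raise VolumeReadError(f"cannot read {path}: {exc}") from exc

    arr = sitk.GetArrayFromImage(img)  # axes (z, y, x) = image axes reversed
    if np.issubdtype(arr.dtype, np.floating):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-6):
            raise FormatError(f"{path} contains non-integer voxel values")
        arr = rounded.astype(np.int32)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path} has unsupported voxel type {arr.dtype}")

    direction = np.array(img.GetDirection(), dtype=float).reshape(3, 3)
    layout = _canonical_layout(direction, str(path))
    spacing_img = img.GetSpacing()  # per image axis (x, y, z)

    # array axis for image axis j is (2 - j)
    transpose = [2 - j for j, _ in layout]
    canon = np.transpose(arr, transpose)
    for c, (_, flip) in enumerate(layout):
        if flip:
            canon = np.flip(canon, axis=c)
    spacing = tuple(spacing_img[j] for j, _ in layout)
    return LabeledVolume(labels=np.ascontiguousarray(canon), spacing=spacing)


def save_labeled_volume(volume: LabeledVolume, path: str | Path) -> None:
    """Write a canonical volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    The canonical frame is recorded in the orientation metadata (an RAS-like
    direction matrix in ITK's LPS convention); the origin is set to zero.
    """
    arr = volume.labels
    # image axes (x, y, z) = canonical (R, A, S) -> array passed as (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr).astype(np.int16, copy=False))
    img.SetSpacing((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    img.SetDirection((-1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, 1.0))
    sitk.WriteImage(img, str(path))


# --------------------------------------------------------------------------- #
# structure extraction and QC
# --------------------------------------------------------------------------- #

def extract_structure(
    volume: LabeledVolume, label: int
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Binary mask of one labeled structure, with the volume's spacing.

    Raises
    ------
    EmptyStructureError
        If the label has no voxels — distinguishable from an I/O failure.
    """
    mask = volume.labels == int(label)
    if not mask.any():
        raise EmptyStructureError(f"label {label} has no voxels")
    return mask, volume.spacing


def _footprint_area(mask: np.ndarray) -> int:
    """Axial (A x R) footprint pixel count, projecting along the SI axis."""
    return int(mask.any(axis=0).sum())


def qc_segmentation(
    volume: LabeledVolume,
    scheme: LabelScheme,
    config: QCConfig | None = None,
) -> QCReport:
    """Screen a segmentation for errors that would corrupt Cobb measurement.

    Flags raised (report-only; nothing is modified):

    * ``missing_discs`` — an expected disc level with zero voxels while both
      adjacent vertebrae are present;
    * ``extra_components`` — a disc split into more than one connected
      component of at least ``min_component_voxels`` voxels;
    * ``shape_flags`` — a disc whose axial footprint covers less than
      ``min_coverage_fraction`` of the adjacent vertebra's footprint (the
      one-sided collapse failure mode).
    """
    config = config or QCConfig()
    present = volume.present_labels()
    report = QCReport()

    vert_masks: dict[str, np.ndarray] = {}
    for v in scheme.vertebrae:
        if v.value in present:
            vert_masks[v.name] = volume.labels == v.value

    for disc in scheme.discs:
        both_vertebrae = disc.above in vert_masks and disc.below in vert_masks
        if disc.value not in present:
            if both_vertebrae:
                report.missing_discs.append(disc.name)
            continue
        mask = volume.labels == disc.value

        labeled, n_comp = ndimage.label(mask)
        if n_comp > 1:
            sizes = ndimage.sum_labels(mask, labeled, index=range(1, n_comp + 1))
            big = int((sizes >= config.min_component_voxels).sum())
            if big > 1:
                report.extra_components[disc.name] = big - 1

        ref = vert_masks.get(disc.above)
        if ref is None:
            ref = vert_masks.get(disc.below)
        if ref is not None:
            ref_area = _footprint_area(ref)
            if ref_area > 0:
                coverage = _footprint_area(mask) / ref_area
                if coverage < config.min_coverage_fraction:
                    report.shape_flags.setdefault(disc.name, []).append(
                        f"in-plane coverage {coverage:.2f} < {config.min_coverage_fraction:.2f}"
                    )
    return report
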