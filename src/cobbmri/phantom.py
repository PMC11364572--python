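"""Synthetic lumbar-spine phantoms with analytically known Cobb angles.

A phantom is a stack of elliptic-cylinder vertebral bodies separated by
discs, rasterized into a canonical (S, A, R) label volume.  Every interface
between structures is a plane whose coronal tilt is configured per vertebral
endplate, so the endplate angle table, all candidate Cobb angles and the
maximal Cobb angle are known in closed form before any voxel exists.  A
global sagittal tilt rotates the whole stack about the LR axis analytically
(before rasterization), which leaves all true coronal angles untouched.

Supported degradations, emulating what real segmentations exhibit:

* smooth seeded jitter of every interface surface (boundary noise),
* a disc collapsed to a fraction of the endplate on one side (the failure
  mode that trips the coverage QC heuristic),
* nearest-neighbour global rotations of the finished volume.

The phantom stands in for clinical scans: it reproduces the labeled-volume
contract and the geometry of a scoliotic curve, not MRI intensities,
posterior elements, or segmentation texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ClippedContentWarning, InfeasibleConfigError
from .mask_io import LabeledVolume, LabelScheme

__all__ = [
    "PhantomConfig",
    "CollapseDefect",
    "PhantomTruth",
    "generate_phantom",
    "apply_global_rotation",
    "simulate_readers",
]


@dataclass(frozen=True)
class CollapseDefect:
    """Collapse one disc to ``coverage`` of its LR extent (kept on the left)."""

    level: str
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage fraction must be in (0, 1]")


@dataclass
class PhantomConfig:
    """Geometry and degradation settings for one phantom.

    ``endplate_tilts_deg`` lists, per vertebra cranial -> caudal, the coronal
    tilt of its (superior, inferior) endplate in degrees.  Adjacent structures
    share interfaces: the inferior endplate of vertebra *i* is the upper
    surface of disc *i*, whose lower surface is the superior endplate of
    vertebra *i+1*.  Default dimensions are plausible lumbar values:
    40 x 30 mm elliptic body cross-section, 28 mm body height, 10 mm disc
    height.  Default spacing matches a high-resolution sagittal acquisition:
    fine in-plane (SI, AP), coarse across sagittal slices (LR).
    """

    n_vertebrae: int = 5
    endplate_tilts_deg: list[tuple[float, float]] | None = None
    sagittal_tilt_deg: float = 0.0
    body_lr_mm: float = 40.0
    body_ap_mm: float = 30.0
    body_height_mm: float = 28.0
    disc_height_mm: float = 10.0
    spacing: tuple[float, float, float] = (0.47, 0.47, 0.90)
    collapse: CollapseDefect | None = None
    noise_mm: float = 0.2
    noise_scale_mm: float = 8.0
    margin_mm: float = 8.0
    seed: int = 0
    vertebra_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_vertebrae < 2:
            raise ValueError("need at least two vertebrae")
        if self.endplate_tilts_deg is None:
            self.endplate_tilts_deg = [(0.0, 0.0)] * self.n_vertebrae
        if len(self.endplate_tilts_deg) != self.n_vertebrae:
            raise ValueError("one (sup, inf) tilt pair per vertebra required")
        for sup, inf in self.endplate_tilts_deg:
            if not (abs(sup) < 45 and abs(inf) < 45):
                raise ValueError("endplate tilts must lie in (-45, 45) degrees")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.vertebra_names is None:
            self.vertebra_names = [f"L{i + 1}" for i in range(self.n_vertebrae)]
        if len(self.vertebra_names) != self.n_vertebrae:
            raise ValueError("one name per vertebra required")

    @classmethod
    def smooth_c_curve(
        cls,
        max_cobb_deg: float,
        plateau_fractions: tuple[float, float] = (0.15, 0.15),
        direction: int = 1,
        **kwargs,
    ) -> "PhantomConfig":
        """Single smooth C-curve with the given maximal Cobb angle.

        Disc tilts progress monotonically from ``-max/2`` to ``+max/2``
        cranio-caudally (times ``direction``); the discs adjacent to the end
        discs are tilted only ``plateau_fractions`` of the half-range less
        than the extremes.  This is the typical degenerative single-curve
        morphology: the end vertebrae are the most tilted and measuring one
        level off the apex pair changes the angle only gradually.
        """
        d1, d2 = plateau_fractions
        shape = [-1.0, -1.0 + d1, 1.0 - d2, 1.0]
        tilts = [direction * x * max_cobb_deg / 2.0 for x in shape]
        return cls.from_disc_tilts(tilts, **kwargs)

    @classmethod
    def from_disc_tilts(cls, disc_tilts_deg: Sequence[float], **kwargs) -> "PhantomConfig":
        """Curve specified by one coronal tilt per disc (parallel-surfaced,
        uniformly tilted discs, i.e. the wedging sits in the vertebrae).

        Disc *i*'s upper and lower surfaces both carry ``disc_tilts_deg[i]``;
        the terminal endplates (top of the first vertebra, bottom of the last)
        repeat the adjacent disc tilt.
        """
        t = [float(x) for x in disc_tilts_deg]
        n = len(t) + 1
        tilts = [(t[max(i - 1, 0)], t[min(i, len(t) - 1)]) for i in range(n)]
        return cls(n_vertebrae=n, endplate_tilts_deg=tilts, **kwargs)

    def scheme(self) -> LabelScheme:
        return LabelScheme.spider_like(list(self.vertebra_names))


@dataclass
class PhantomTruth:
    """Closed-form ground truth for a generated phantom."""

    disc_levels: list[str]                      # cranial -> caudal
    disc_angles: dict[str, dict[str, float]]    # per disc: upper/lower x coronal/sagittal
    candidate_matrix: dict[tuple[str, str], float]  # (top, bottom) -> Cobb degrees
    vertebra_order: list[str] = field(default_factory=list)  # cranial -> caudal
    max_cobb_deg: float = 0.0
    max_levels: tuple[str, str] = ("", "")
    voxel_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.candidate_matrix:
            best = self._argmax()
            self.max_levels = best
            self.max_cobb_deg = self.candidate_matrix[best]

    def _argmax(self) -> tuple[str, str]:
        # mirror of max_cobb's tie-break: angle, then span, then cranial top
        order = {lvl: i for i, lvl in enumerate(self.vertebra_order)}
        def key(item):
            (top, bottom), angle = item
            return (angle, order[bottom] - order[top], -order[top])
        return max(self.candidate_matrix.items(), key=key)[0]

    def angle_at(self, top: str, bottom: str) -> float:
        return self.candidate_matrix[(top, bottom)]

    def to_dict(self) -> dict:
        return {
            "disc_levels": self.disc_levels,
            "disc_angles": self.disc_angles,
            "candidate_matrix": {f"{t}|{b}": a for (t, b), a in self.candidate_matrix.items()},
            "vertebra_order": self.vertebra_order,
            "max_cobb_deg": self.max_cobb_deg,
            "max_levels": list(self.max_levels),
            "voxel_counts": self.voxel_counts,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PhantomTruth":
        matrix = {tuple(k.split("|")): float(v) for k, v in doc["candidate_matrix"].items()}
        return cls(
            disc_levels=list(doc["disc_levels"]),
            disc_angles={k: dict(v) for k, v in doc["disc_angles"].items()},
            candidate_matrix=matrix,
            vertebra_order=list(doc["vertebra_order"]),
            voxel_counts={k: int(v) for k, v in doc.get("voxel_counts", {}).items()},
        )

    def runner_up_gap(self) -> float:
        """True max minus the best candidate at any *other* level pair."""
        others = [a for lv, a in self.candidate_matrix.items() if lv != self.max_levels]
        return self.max_cobb_deg - max(others) if others else float("inf")


def _interface_tilts(config: PhantomConfig) -> list[float]:
    """Coronal tilt (degrees) of interface m, cranial -> caudal.

    Interface 2i is the superior endplate of vertebra i, interface 2i+1 its
    inferior endplate; consecutive structures share interfaces.
    """
    tilts: list[float] = []
    for sup, inf in config.endplate_tilts_deg:
        tilts.extend([sup, inf])
    return tilts


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  spacing: tuple[float, float], amp_mm: float, scale_mm: float) -> np.ndarray:
    """Smooth bounded jitter field over an (A, R) grid, amplitude <= amp_mm."""
    if amp_mm <= 0:
        return np.zeros(shape)
    coarse = tuple(max(2, int(np.ceil(shape[d] * spacing[d] / scale_mm)) + 1) for d in (0, 1))
    base = rng.uniform(-amp_mm, amp_mm, size=coarse)
    zoom = (shape[0] / coarse[0], shape[1] / coarse[1])
    out = ndimage.zoom(base, zoom, order=1, mode="nearest", grid_mode=True)
    return out[: shape[0], : shape[1]]


def generate_phantom(config: PhantomConfig) -> tuple[LabeledVolume, PhantomTruth]:
    """Rasterize the phantom and return it with its analytic ground truth.

    Deterministic for a fixed config (including seed).
    """
    n = config.n_vertebrae
    names = list(config.vertebra_names)
    scheme = config.scheme()
    tilts_deg = _interface_tilts(config)
    tans = [math.tan(math.radians(t)) for t in tilts_deg]
    g = math.radians(config.sagittal_tilt_deg)

    heights = []
    for i in range(n):
        heights.append(config.body_height_mm)
        if i < n - 1:
            heights.append(config.disc_height_mm)
    total = sum(heights)
    half_lr = config.body_lr_mm / 2.0
    half_ap = config.body_ap_mm / 2.0

    # feasibility: adjacent interfaces of one structure must not cross inside
    # the ellipse, even at maximal boundary jitter
    for k, h in enumerate(heights):
        gap = h - abs(tans[k] - tans[k + 1]) * half_lr - 2.0 * config.noise_mm
        if gap <= 0.1:
            raise InfeasibleConfigError(
                f"structure {k} (height {h} mm) pinched to {gap:.2f} mm by tilts "
                f"{tilts_deg[k]:+.1f}/{tilts_deg[k + 1]:+.1f} degrees"
            )

    # Segments follow a bent center line: each structure is an elliptic
    # cylinder rigidly rotated about the AP axis by the mean tilt of its two
    # end surfaces, and laterally offset so consecutive segments stack along
    # the curve.  (A rigid rotation is what a scoliotic curve does to its
    # vertebrae and discs; modeling the tilt as a shear with vertical walls
    # would bias the surface-PCA fit by construction.)
    depth = np.concatenate([[0.0], np.cumsum(heights)])
    z = total / 2.0 - depth                           # interface heights, stack frame
    n_struct = 2 * n - 1
    seg_tilt = [math.atan(0.5 * (tans[k] + tans[k + 1])) for k in range(n_struct)]
    offsets = np.zeros(2 * n)                         # lateral (R) offset per interface
    for k in range(n_struct):
        offsets[k + 1] = offsets[k] - heights[k] * math.tan(seg_tilt[k])
    offsets -= offsets.mean()
    seg_center_r = [(offsets[k] + offsets[k + 1]) / 2.0 for k in range(n_struct)]
    seg_center_z = [(z[k] + z[k + 1]) / 2.0 for k in range(n_struct)]

    # feasibility: the two end planes of a structure must not cross inside it
    for k, h in enumerate(heights):
        rr = np.linspace(seg_center_r[k] - half_lr, seg_center_r[k] + half_lr, 33)
        upper = z[k] - tans[k] * (rr - offsets[k])
        lower = z[k + 1] - tans[k + 1] * (rr - offsets[k + 1])
        gap = float((upper - lower).min()) - 2.0 * config.noise_mm
        if gap <= 0.1:
            raise InfeasibleConfigError(
                f"structure {k} (height {h} mm) pinched to {gap:.2f} mm by tilts "
                f"{tilts_deg[k]:+.1f}/{tilts_deg[k + 1]:+.1f} degrees"
            )

    # volume extents from the rotated stack's bounding box
    max_tan = max(abs(t) for t in tans) if tans else 0.0
    max_off = float(np.abs(offsets).max())
    half_s = (total / 2) * abs(math.cos(g)) + half_ap * abs(math.sin(g)) \
        + max_tan * half_lr + config.margin_mm
    half_a = (total / 2) * abs(math.sin(g)) + half_ap * abs(math.cos(g)) + config.margin_mm
    half_r = half_lr + max_off + config.margin_mm
    sp = config.spacing
    dims = tuple(int(np.ceil(2 * h / s)) for h, s in zip((half_s, half_a, half_r), sp))

    s = (np.arange(dims[0]) - (dims[0] - 1) / 2.0) * sp[0]
    a = (np.arange(dims[1]) - (dims[1] - 1) / 2.0) * sp[1]
    r = (np.arange(dims[2]) - (dims[2] - 1) / 2.0) * sp[2]

    # world -> phantom frame: rotate (S, A) by the sagittal tilt; R unchanged
    cg, sg = math.cos(g), math.sin(g)
    s_p = cg * s[:, None] + sg * a[None, :]          # (S, A)
    a_p = -sg * s[:, None] + cg * a[None, :]         # (S, A)
    r_p = r                                           # (R,)

    rng = np.random.default_rng(config.seed)
    surfaces = []
    for m in range(2 * n):
        eta = _smooth_noise(rng, (dims[1], dims[2]), (sp[1], sp[2]),
                            config.noise_mm, config.noise_scale_mm)
        surfaces.append(z[m] - tans[m] * (r_p[None, :] - offsets[m]) + eta)   # (A, R)

    structure_labels: list[int] = []
    structure_names: list[str] = []
    for i in range(n):
        structure_labels.append(scheme.vertebra_value(names[i]))
        structure_names.append(names[i])
        if i < n - 1:
            d = scheme.discs[i]
            structure_labels.append(d.value)
            structure_names.append(d.name)

    labels = np.zeros(dims, dtype=np.int16)
    sp3 = s_p[:, :, None]
    ap2 = (a_p[:, :, None] / half_ap) ** 2
    for k, value in enumerate(structure_labels):
        # elliptic cross-section in the segment's own (rotated, offset) frame
        cphi, sphi = math.cos(seg_tilt[k]), math.sin(seg_tilt[k])
        r_loc = -sphi * (sp3 - seg_center_z[k]) + cphi * (r_p[None, None, :] - seg_center_r[k])
        inside = ap2 + (r_loc / half_lr) ** 2 <= 1.0
        region = inside & (sp3 <= surfaces[k][None, :, :]) & (sp3 > surfaces[k + 1][None, :, :])
        if config.collapse is not None and structure_names[k] == config.collapse.level:
            r_cut = half_lr * (2.0 * config.collapse.coverage - 1.0)
            region &= r_loc <= r_cut
        labels[region] = value

    volume = LabeledVolume(labels=labels, spacing=sp)

    # ------------------------------------------------------------------ truth
    def surface_angles(tilt_deg: float) -> tuple[float, float]:
        # implicit surface gradient in world frame: (cos g, sin g, tan(tilt))
        t = math.tan(math.radians(tilt_deg))
        v = np.array([cg, sg, t])
        v /= np.linalg.norm(v)
        if v[0] < 0:
            v = -v
        return math.degrees(math.asin(v[2])), math.degrees(math.asin(v[1]))

    disc_levels = [d.name for d in scheme.discs]
    disc_angles: dict[str, dict[str, float]] = {}
    for i, level in enumerate(disc_levels, start=1):
        up_cor, up_sag = surface_angles(tilts_deg[2 * i - 1])
        lo_cor, lo_sag = surface_angles(tilts_deg[2 * i])
        disc_angles[level] = {
            "upper_coronal": up_cor, "lower_coronal": lo_cor,
            "upper_sagittal": up_sag, "lower_sagittal": lo_sag,
        }

    candidate_matrix: dict[tuple[str, str], float] = {}
    for i in range(1, n):           # disc i: between names[i-1] and names[i]
        for j in range(i + 1, n):
            top, bottom = names[i], names[j - 1]
            theta = abs(
                disc_angles[disc_levels[i - 1]]["lower_coronal"]
                - disc_angles[disc_levels[j - 1]]["upper_coronal"]
            )
            candidate_matrix[(top, bottom)] = theta

    counts = {nm: int((labels == val).sum())
              for nm, val in zip(structure_names, structure_labels)}
    truth = PhantomTruth(
        disc_levels=disc_levels,
        disc_angles=disc_angles,
        candidate_matrix=candidate_matrix,
        vertebra_order=names,
        voxel_counts=counts,
    )
    return volume, truth


def apply_global_rotation(volume: LabeledVolume, axis: str, degrees: float) -> LabeledVolume:
    """Nearest-neighbour rotation of the label volume about its center.

    ``axis`` is the anatomical rotation axis: ``"LR"`` rotates in the
    sagittal (S, A) plane, ``"AP"`` in the coronal (S, R) plane.  Emits
    :class:`ClippedContentWarning` if structure voxels leave the grid.
    """
    if abs(degrees) >= 30:
        raise ValueError("rotations are limited to |degrees| < 30")
    planes = {"LR": (0, 1), "AP": (0, 2)}
    if axis not in planes:
        raise ValueError(f"axis must be 'LR' or 'AP', got {axis!r}")
    rotated = ndimage.rotate(
        volume.labels, degrees, axes=planes[axis], reshape=False, order=0,
        mode="constant", cval=0,
    )
    before = int((volume.labels > 0).sum())
    after = int((rotated > 0).sum())
    if after < before * 0.999:
        import warnings

        warnings.warn(
            f"rotation clipped {before - after} structure voxels", ClippedContentWarning,
            stacklevel=2,
        )
    return LabeledVolume(labels=rotated, spacing=volume.spacing)


def simulate_readers(
    truths: Sequence[PhantomTruth] | dict[str, PhantomTruth],
    n_readers: int = 3,
    angle_noise_sd: float = 2.5,
    level_error_prob: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated manual Cobb measurements on phantoms.

    Each reader starts from the true maximal curve; independently for the top
    and bottom level, with probability ``level_error_prob`` they pick an
    adjacent level instead (clamped to levels that exist; bottom is raised to
    the top if the perturbations cross).  The reported angle is the true
    angle at the chosen levels plus Gaussian noise, floored at zero.

    Returns a tidy frame with columns ``case, source, top, bottom, angle``.
    """
    if n_readers < 2:
        raise ValueError("need at least two readers")
    if isinstance(truths, dict):
        items = list(truths.items())
    else:
        items = [(f"case{i:03d}", t) for i, t in enumerate(truths)]
    rng = np.random.default_rng(seed)
    rows = []
    for case, truth in items:
        order = truth.vertebra_order
        idx = {v: i for i, v in enumerate(order)}
        valid_tops = sorted({idx[t] for t, _ in truth.candidate_matrix})
        valid_bottoms = sorted({idx[b] for _, b in truth.candidate_matrix})
        t0, b0 = idx[truth.max_levels[0]], idx[truth.max_levels[1]]
        for reader in range(1, n_readers + 1):
            t, b = t0, b0
            if rng.random() < level_error_prob:
                t = _shift(t, valid_tops, rng)
            if rng.random() < level_error_prob:
                b = _shift(b, valid_bottoms, rng)
            if t > b:
                b = t
            top, bottom = order[t], order[b]
            angle = truth.angle_at(top, bottom) + rng.normal(0.0, angle_noise_sd)
            rows.append(
                {"case": case, "source": f"reader{reader}", "top": top,
                 "bottom": bottom, "angle": max(0.0, float(angle))}
            )
    return pd.DataFrame(rows)


def _shift(i: int, valid: list[int], rng: np.random.Generator) -> int:
    step = 1 if rng.random() < 0.5 else -1
    if i + step not in valid:
        step = -step
    return i + step if i + step in valid else i
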