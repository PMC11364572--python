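"""Reliability statistics for paired Cobb measurements.

Implements the agreement machinery used to validate automatic Cobb
measurement against human readers: mean absolute error, the two-way
random-effects absolute-agreement single-measurement intraclass correlation
ICC(2,1) with its F-based 95% confidence interval (McGraw & Wong), the Koo &
Li interpretation bands (0.50 / 0.75 / 0.90 = poor / moderate / good /
excellent), Bland–Altman bias and limits of agreement against the 5°
clinically accepted Cobb error, consensus vertebral levels for an odd reader
panel, per-reader level-agreement tabulation, and the human–AI acceptance
simulation (a measurement is accepted when it is strictly within the
tolerance of the automatic value at the same levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnavailableLevelError, UnsupportedConfigurationError

__all__ = [
    "MeasurementSet",
    "ICCResult",
    "BlandAltmanResult",
    "AcceptanceResult",
    "AgreementReport",
    "consensus_level",
    "mae",
    "icc",
    "icc_band",
    "bland_altman",
    "acceptance_simulation",
    "level_agreement_table",
]

_COLUMNS = ["case", "source", "top", "bottom", "angle"]


@dataclass
class MeasurementSet:
    """Tidy table of Cobb measurements: one row per (case, source, levels).

    ``source`` identifies who produced the row (a reader id or the
    algorithm); several rows per (case, source) are allowed as long as they
    are at distinct level pairs (the algorithm reports one angle per level
    pair it is asked about).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement set lacks columns {missing}")
        df = df[_COLUMNS].copy()
        df["angle"] = df["angle"].astype(float)
        if (df["angle"] < 0).any():
            raise ValueError("angles must be non-negative")
        dup = df.duplicated(subset=["case", "source", "top", "bottom"])
        if dup.any():
            raise ValueError(
                f"duplicate (case, source, top, bottom) rows: {df[dup].to_dict('records')}"
            )
        self.data = df

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def sources(self) -> list[str]:
        return sorted(self.data["source"].unique())

    def cases(self) -> list[str]:
        return sorted(self.data["case"].astype(str).unique())

    def lookup(self, case, source=None, top=None, bottom=None) -> pd.DataFrame:
        df = self.data
        sel = df["case"] == case
        for col, val in (("source", source), ("top", top), ("bottom", bottom)):
            if val is not None:
                sel &= df[col] == val
        return df[sel]


def consensus_level(levels: Sequence[str], order: Sequence[str]) -> str:
    """Median vertebral level of an odd reader panel.

    ``order`` gives the cranio-caudal ordering of level names.  With three
    mutually distinct choices this is the middle level; an even panel size is
    refused (the median may fall between levels).
    """
    if len(levels) < 3 or len(levels) % 2 == 0:
        raise UnsupportedConfigurationError(
            f"consensus requires an odd panel of >= 3 readers, got {len(levels)}"
        )
    idx = {name: i for i, name in enumerate(order)}
    try:
        ranks = sorted(idx[lv] for lv in levels)
    except KeyError as exc:
        raise UnsupportedConfigurationError(f"level {exc} not in the given ordering") from exc
    return list(order)[ranks[len(ranks) // 2]]


def mae(a: Sequence[float], b: Sequence[float], ddof: int = 0) -> tuple[float, float]:
    """Mean and SD of absolute pairwise differences |a - b|.

    The SD is the population SD (``ddof=0``) by default.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("mae needs two equally sized, non-empty vectors")
    d = np.abs(a - b)
    return float(d.mean()), float(d.std(ddof=ddof))


@dataclass(frozen=True)
class ICCResult:
    estimate: float            # clipped to [0, 1]
    ci95: tuple[float, float]
    band: str
    raw_estimate: float        # may be negative
    clipped: bool
    n_cases: int
    n_raters: int

    def to_dict(self) -> dict:
        return {
            "icc": self.estimate,
            "ci95": list(self.ci95),
            "band": self.band,
            "clipped": self.clipped,
            "n_cases": self.n_cases,
            "n_raters": self.n_raters,
        }


def icc_band(value: float) -> str:
    if value < 0.50:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.90:
        return "good"
    return "excellent"


def icc(ratings: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``ratings`` is a cases x raters matrix with no missing cells.  The 95%
    confidence interval follows McGraw & Wong's F-based formulas with the
    Satterthwaite degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D cases x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError(f"need >= 5 cases and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported (no imputation)")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    raw = (msr - mse) / denom if denom > 0 else 1.0

    # confidence interval (McGraw & Wong, ICC(A,1))
    if mse <= 0 and msc <= 0:
        lo, hi = 1.0, 1.0  # raters agree exactly on every case
    else:
        fc = msc / mse if mse > 0 else np.inf
        a_ = k * raw / (n * (1 - raw)) if raw < 1 else np.inf
        b_ = 1 + k * raw * (n - 1) / (n * (1 - raw)) if raw < 1 else np.inf
        if not np.isfinite(a_) or not np.isfinite(fc):
            lo, hi = 1.0, 1.0
        else:
            vn = (k - 1) * (n - 1) * (k * raw * fc + n * (1 + (k - 1) * raw) - k * raw) ** 2
            vd = (n - 1) * (k * raw * fc) ** 2 + (
                n * (1 + (k - 1) * raw) - k * raw
            ) ** 2
            v = vn / vd
            f2u = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2l = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f2u * mse) / (
                f2u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f2l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2l * msr
            )
    raw = float(raw)
    estimate = min(max(raw, 0.0), 1.0)
    return ICCResult(
        estimate=estimate,
        ci95=(float(max(min(lo, 1.0), -1.0)), float(min(hi, 1.0))),
        band=icc_band(estimate),
        raw_estimate=raw,
        clipped=raw < 0,
        n_cases=n,
        n_raters=k,
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "sd_diff": self.sd_diff,
            "n": self.n,
        }


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    plot: str | Path | None = None,
    clinical_band: float = 5.0,
) -> BlandAltmanResult:
    """Bland–Altman bias and 1.96-SD limits of agreement for a - b.

    When ``plot`` is given, renders differences against means with the bias
    (solid), the limits (dotted) and the clinical ±``clinical_band``° lines
    (red).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("bland_altman needs >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    res = BlandAltmanResult(
        bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
        sd_diff=sd, n=len(d),
    )
    if plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        ax.scatter((a + b) / 2, d, s=18, alpha=0.7, edgecolor="none")
        ax.axhline(res.bias, color="black", label=f"bias {res.bias:+.1f}\N{DEGREE SIGN}")
        for y in (res.loa_lower, res.loa_upper):
            ax.axhline(y, color="black", linestyle=":")
        for y in (-clinical_band, clinical_band):
            ax.axhline(y, color="red", linewidth=1)
        ax.set_xlabel("mean of measurements (\N{DEGREE SIGN})")
        ax.set_ylabel("difference (\N{DEGREE SIGN})")
        ax.legend(loc="upper right", frameon=False)
        fig.savefig(str(plot), dpi=150, bbox_inches="tight")
        plt.close(fig)
    return res


@dataclass
class AcceptanceResult:
    fraction_accepted: float
    tolerance: float
    verdicts: pd.DataFrame          # case, source, top, bottom, manual, automatic, accepted
    rejected: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fraction_accepted": self.fraction_accepted,
            "tolerance_deg": self.tolerance,
            "n": int(len(self.verdicts)),
            "rejected": self.rejected,
        }


def acceptance_simulation(
    manual: MeasurementSet,
    automatic: MeasurementSet,
    tolerance: float = 5.0,
) -> AcceptanceResult:
    """Simulated human–AI combined workflow.

    For every manual measurement, the automatic angle *at the same levels* is
    looked up; the measurement is accepted when the absolute difference is
    strictly below ``tolerance`` (rejections would trigger a manual repeat).
    """
    rows = []
    missing: list[str] = []
    for rec in manual.data.itertuples(index=False):
        match = automatic.lookup(rec.case, top=rec.top, bottom=rec.bottom)
        if match.empty:
            missing.append(f"{rec.case}:{rec.top}-{rec.bottom}")
            continue
        auto_angle = float(match["angle"].iloc[0])
        rows.append(
            {
                "case": rec.case, "source": rec.source, "top": rec.top,
                "bottom": rec.bottom, "manual": float(rec.angle),
                "automatic": auto_angle,
                "accepted": abs(float(rec.angle) - auto_angle) < tolerance,
            }
        )
    if missing:
        raise UnavailableLevelError(
            f"no automatic measurement at levels of {len(missing)} manual rows", levels=missing
        )
    verdicts = pd.DataFrame(rows)
    rejected = [
        {k: (v.item() if hasattr(v, "item") else v) for k, v in rec.items()}
        for rec in verdicts[~verdicts["accepted"]].to_dict("records")
    ]
    return AcceptanceResult(
        fraction_accepted=float(verdicts["accepted"].mean()),
        tolerance=tolerance,
        verdicts=verdicts,
        rejected=rejected,
    )


_BUCKETS = ["same_level", "one_level", "two_levels", "more_than_two"]


def level_agreement_table(
    manual: MeasurementSet,
    reference: MeasurementSet,
    order: Sequence[str],
) -> pd.DataFrame:
    """Per-source distribution of vertebral-level distance to the reference.

    The distance of one measurement is |Δtop| + |Δbottom| in level steps
    relative to the reference measurement of the same case (e.g. the
    algorithm's maximal-angle levels); distances 0, 1, 2 and >2 are bucketed.
    Returns a sources x buckets frame of fractions.
    """
    idx = {name: i for i, name in enumerate(order)}
    ref_rows = {}
    for rec in reference.data.itertuples(index=False):
        ref_rows[rec.case] = rec
    missing = sorted(set(manual.data["case"]) - set(ref_rows))
    if missing:
        raise ValueError(f"cases without reference measurement: {missing}")

    out: dict[str, dict[str, float]] = {}
    for source, grp in manual.data.groupby("source"):
        counts = dict.fromkeys(_BUCKETS, 0)
        for rec in grp.itertuples(index=False):
            ref = ref_rows[rec.case]
            dist = abs(idx[rec.top] - idx[ref.top]) + abs(idx[rec.bottom] - idx[ref.bottom])
            bucket = _BUCKETS[min(dist, 3)]
            counts[bucket] += 1
        total = len(grp)
        out[str(source)] = {k: v / total for k, v in counts.items()}
    return pd.DataFrame(out).T[_BUCKETS]


@dataclass
class AgreementReport:
    """Bundle of the agreement statistics for one paired comparison."""

    mae_mean: float
    mae_sd: float
    icc: ICCResult
    bland_altman: BlandAltmanResult
    fraction_within_tolerance: float
    tolerance: float = 5.0

    @classmethod
    def from_pairs(
        cls,
        a: Sequence[float],
        b: Sequence[float],
        ratings: np.ndarray | None = None,
        tolerance: float = 5.0,
        plot: str | Path | None = None,
    ) -> "AgreementReport":
        """Agreement between two paired measurement vectors.

        ``ratings`` (cases x raters) defaults to ``column_stack([a, b])``;
        pass a wider matrix to report a multi-rater ICC next to the pairwise
        error statistics.
        """
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        m, sd = mae(a, b)
        mat = np.column_stack([a, b]) if ratings is None else np.asarray(ratings, float)
        ba = bland_altman(a, b, plot=plot, clinical_band=tolerance)
        within = float((np.abs(a - b) < tolerance).mean())
        return cls(
            mae_mean=m, mae_sd=sd, icc=icc(mat), bland_altman=ba,
            fraction_within_tolerance=within, tolerance=tolerance,
        )

    def to_dict(self) -> dict:
        return {
            "mae_deg": self.mae_mean,
            "mae_sd_deg": self.mae_sd,
            "icc": self.icc.to_dict(),
            "bland_altman": self.bland_altman.to_dict(),
            "fraction_within_tolerance": self.fraction_within_tolerance,
            "tolerance_deg": self.tolerance,
        }
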