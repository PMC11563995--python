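"""Relative arterial contribution estimation and cohort aggregation.

The paired design makes the control hip (both arteries infused) the
denominator: its enhancement represents the total MFCA + LFCA supply of a
region, so the infused artery's relative contribution on the experimental
hip is the experimental/control enhancement ratio, clipped to [0, 1] and
expressed in percent. The other artery's share is the complement, so every
estimate and every summary pair sums to exactly 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enhancement import EnhancementMeasure
from .errors import LowControlSignalError, ValidationError
from .regions import TABLE_CELLS, cell_name, other_artery

__all__ = [
    "ContributionEstimate",
    "CohortSummary",
    "specimen_contribution",
    "aggregate_cohort",
    "build_table",
    "DEFAULT_CONTROL_FLOOR",
]

#: Minimum admissible control-hip enhancement (normalized units); ratios with
#: a smaller denominator are unreliable and are rejected or QC-flagged.
DEFAULT_CONTROL_FLOOR = 0.05

QC_OK = "ok"
QC_LOW_CONTROL = "low_control_signal"


@dataclass(frozen=True)
class ContributionEstimate:
    """Per-specimen, per-cell MFCA/LFCA percentages (sum exactly 100)."""

    specimen_id: str
    region: str
    subregion: str | None
    mfca_pct: float
    lfca_pct: float
    qc_flag: str = QC_OK

    def __post_init__(self) -> None:
        if not (0.0 <= self.mfca_pct <= 100.0 and 0.0 <= self.lfca_pct <= 100.0):
            raise ValidationError("percentages must lie in [0, 100]")
        if self.mfca_pct + self.lfca_pct != 100.0:
            raise ValidationError("MFCA% + LFCA% must equal 100 exactly")
        if self.qc_flag not in (QC_OK, QC_LOW_CONTROL):
            raise ValidationError(f"unknown qc_flag {self.qc_flag!r}")


@dataclass(frozen=True)
class CohortSummary:
    """Cohort descriptive statistics of one artery's percentage in one cell."""

    region: str
    subregion: str | None
    artery: str
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float
    range_min: float
    range_max: float
    n: int

    def __post_init__(self) -> None:
        if not self.iqr_low <= self.median <= self.iqr_high:
            raise ValidationError("IQR must bracket the median")


def specimen_contribution(
    e_exp: EnhancementMeasure,
    e_ctrl: EnhancementMeasure,
    infused: str,
    specimen_id: str = "",
    floor: float = DEFAULT_CONTROL_FLOOR,
    mode: str = "strict",
) -> ContributionEstimate:
    """Relative contribution of the infused artery in one cell.

    infused% = 100 * clip(e_exp / e_ctrl, 0, 1); the other artery's share is
    the complement. A control enhancement at or below ``floor`` raises
    :class:`LowControlSignalError` in strict mode, or yields a
    ``low_control_signal``-flagged estimate (excluded from aggregation) in
    lenient mode.
    """
    if (e_exp.region, e_exp.subregion) != (e_ctrl.region, e_ctrl.subregion):
        raise ValidationError(
            f"region mismatch: experimental ({e_exp.region}, {e_exp.subregion}) vs "
            f"control ({e_ctrl.region}, {e_ctrl.subregion})"
        )
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be strict|lenient, got {mode!r}")
    qc = QC_OK
    denom = e_ctrl.enhancement
    if denom <= floor:
        if mode == "strict":
            raise LowControlSignalError(
                f"control enhancement {denom:.4g} <= floor {floor:g} in cell "
                f"({e_exp.region}, {e_exp.subregion}) of specimen {specimen_id or '<unknown>'}"
            )
        qc = QC_LOW_CONTROL
        denom = max(denom, floor)  # keep the flagged value bounded
    infused_pct = 100.0 * float(np.clip(e_exp.enhancement / denom, 0.0, 1.0))
    pcts = {infused: infused_pct, other_artery(infused): 100.0 - infused_pct}
    return ContributionEstimate(
        specimen_id=specimen_id,
        region=e_exp.region,
        subregion=e_exp.subregion,
        mfca_pct=pcts["MFCA"],
        lfca_pct=pcts["LFCA"],
        qc_flag=qc,
    )


def _cell_values(
    estimates: list[ContributionEstimate], region: str, subregion: str | None, artery: str
) -> np.ndarray:
    vals = [
        e.mfca_pct if artery == "MFCA" else e.lfca_pct
        for e in estimates
        if e.region == region and e.subregion == subregion and e.qc_flag == QC_OK
    ]
    return np.asarray(vals, dtype=float)


def aggregate_cohort(
    estimates: list[ContributionEstimate],
    region: str,
    subregion: str | None = None,
    artery: str = "MFCA",
) -> CohortSummary:
    """Descriptive summary of one cell across the cohort: mean, sample SD
    (n-1), median, 25th/75th percentiles by linear interpolation, range.

    Statistics are computed on the MFCA percentages; the LFCA summary is the
    exact complement (mean/median/quartiles reflected around 100, same SD),
    so paired summary columns sum to 100 exactly. QC-flagged estimates are
    excluded; at least 2 usable estimates required.
    """
    if artery not in ("MFCA", "LFCA"):
        raise ValueError(f"artery must be MFCA|LFCA, got {artery!r}")
    vals = _cell_values(estimates, region, subregion, "MFCA")
    if len(vals) < 2:
        raise ValidationError(
            f"cell ({region}, {subregion}) has {len(vals)} usable estimate(s); need >= 2"
        )
    q25, q50, q75 = np.percentile(vals, [25, 50, 75], method="linear")
    mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    lo, hi = float(vals.min()), float(vals.max())
    if artery == "LFCA":  # exact complement of the MFCA summary
        mean, q25, q50, q75, lo, hi = (
            100.0 - mean, 100.0 - q75, 100.0 - q50, 100.0 - q25, 100.0 - hi, 100.0 - lo,
        )
        lo, hi = hi, lo
    return CohortSummary(
        region=region,
        subregion=subregion,
        artery=artery,
        mean=mean,
        sd=sd,
        median=float(q50),
        iqr_low=float(q25),
        iqr_high=float(q75),
        range_min=lo,
        range_max=hi,
        n=len(vals),
    )


def build_table(
    summaries: dict[tuple[str, str | None], dict[str, CohortSummary]],
    tests: dict[tuple[str, str | None], "object"] | None = None,
) -> pd.DataFrame:
    """Assemble the 15-row report table (one row per cell, MFCA and LFCA
    summary columns plus the Mann-Whitney p-value).

    ``summaries[cell][artery]`` must cover every report cell for both
    arteries; a missing cell raises with its name.
    """
    missing = [cell_name(r, s) for (r, s) in TABLE_CELLS if (r, s) not in summaries]
    if missing:
        raise ValidationError(f"missing summary cells: {missing}")
    rows = []
    for region, sub in TABLE_CELLS:
        cell = summaries[(region, sub)]
        if "MFCA" not in cell or "LFCA" not in cell:
            raise ValidationError(f"cell {cell_name(region, sub)} lacks both artery summaries")
        m, l = cell["MFCA"], cell["LFCA"]
        test = (tests or {}).get((region, sub))
        rows.append(
            {
                "cell": cell_name(region, sub),
                "region": region,
                "subregion": "" if sub is None else sub,
                "n": m.n,
                "mfca_mean": m.mean,
                "mfca_sd": m.sd,
                "mfca_median": m.median,
                "mfca_iqr_low": m.iqr_low,
                "mfca_iqr_high": m.iqr_high,
                "mfca_range_min": m.range_min,
                "mfca_range_max": m.range_max,
                "lfca_mean": l.mean,
                "lfca_sd": l.sd,
                "lfca_median": l.median,
                "lfca_iqr_low": l.iqr_low,
                "lfca_iqr_high": l.iqr_high,
                "lfca_range_min": l.range_min,
                "lfca_range_max": l.range_max,
                "p_value": math.nan if test is None else float(test.p_value),
                "significant": None if test is None else bool(test.significant),
            }
        )
    return pd.DataFrame(rows)


def format_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the report table."""
    header = (
        f"{'Region of perfusion':<28}{'MFCA mean (SD)':>17}{'MFCA median [IQR]':>24}"
        f"{'LFCA mean (SD)':>17}{'p':>9}"
    )
    lines = [header, "-" * len(header)]
    for _, row in table.iterrows():
        p = row["p_value"]
        p_str = "" if pd.isna(p) else ("<0.001" if p < 0.001 else f"{p:.3f}")
        mfca = f"{row['mfca_mean']:.1f}% ({row['mfca_sd']:.1f}%)"
        med = (
            f"{row['mfca_median']:.1f}% "
            f"[{row['mfca_iqr_low']:.1f}-{row['mfca_iqr_high']:.1f}%]"
        )
        lfca = f"{row['lfca_mean']:.1f}% ({row['lfca_sd']:.1f}%)"
        lines.append(f"{row['cell']:<28}{mfca:>17}{med:>24}{lfca:>17}{p_str:>9}")
    return "\n".join(lines)
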