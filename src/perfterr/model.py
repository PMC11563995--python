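"""Model/Results surface for the territory-contribution analysis.

:class:`ArterialContributionModel` wraps a cohort of paired-hip specimen
image sets; :meth:`fit` runs the full estimation — per-ROI normalized
enhancement, experimental/control ratio with complement, cohort descriptive
statistics and per-cell Mann-Whitney tests — and returns an
:class:`ArterialContributionResults` carrying the estimates, summary table
and diagnostics, in the style of a statsmodels results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import contribution as _contrib
from . import enhancement as _enh
from . import phantom as _phantom
from . import stats as _stats
from .contribution import (
    DEFAULT_CONTROL_FLOOR,
    CohortSummary,
    ContributionEstimate,
    build_table,
    format_table,
)
from .errors import ValidationError
from .regions import TABLE_CELLS, cell_name
from .stats import TestResult
from .volumes import SpecimenImageSet

__all__ = ["ArterialContributionModel", "ArterialContributionResults", "RecoveryReport"]


@dataclass(frozen=True)
class RecoveryReport:
    """Truth-vs-estimate comparison for simulated cohorts."""

    table: pd.DataFrame  # per-cell cohort-mean estimate, truth, abs error (pp)
    mae: float  # mean absolute error over all cells, percentage points

    def region_errors(self) -> pd.Series:
        """Absolute error (pp) for the five region-level rows."""
        t = self.table
        return t.loc[t["subregion"] == "", "abs_error_pp"]


class ArterialContributionModel:
    """Relative arterial contribution model for a cohort of paired hips.

    Parameters
    ----------
    specimens:
        The cohort's specimen image sets (phantom-generated or loaded from
        manifests).
    floor:
        Minimum admissible control-hip enhancement (normalized units).
    qc:
        ``"strict"`` (raise on low control signal) or ``"lenient"`` (flag
        and exclude the affected estimates).
    """

    def __init__(
        self,
        specimens: Sequence[SpecimenImageSet],
        floor: float = DEFAULT_CONTROL_FLOOR,
        qc: str = "strict",
    ) -> None:
        if len(specimens) == 0:
            raise ValidationError("model requires at least one specimen")
        if qc not in ("strict", "lenient"):
            raise ValueError(f"qc must be strict|lenient, got {qc!r}")
        self.specimens = list(specimens)
        self.floor = float(floor)
        self.qc = qc

    @classmethod
    def from_manifests(cls, manifest_paths: Sequence, base_dir=None, **kwargs):
        """Build the model by loading specimen manifests from disk."""
        from .io import load_specimen, read_manifest

        specimens = []
        for path in manifest_paths:
            manifest = read_manifest(path)
            specimens.append(load_specimen(manifest, base_dir or Path(path).parent))
        return cls(specimens, **kwargs)

    @classmethod
    def from_simulation(
        cls,
        cohort: _phantom.CohortConfig | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "ArterialContributionModel":
        """Build the model from a freshly generated phantom cohort; the truth
        table is kept on the model for recovery analysis."""
        cohort = cohort or _phantom.CohortConfig()
        dataset, truth_table = _phantom.generate_cohort(cohort, seed)
        model = cls(dataset.specimens, **kwargs)
        model.truth_table = truth_table
        return model

    truth_table: pd.DataFrame | None = None

    def fit(
        self, tests: bool = True, histograms: bool = False
    ) -> "ArterialContributionResults":
        """Run the estimation pipeline over the cohort."""
        enh_rows = []
        estimates: list[ContributionEstimate] = []
        for spec in self.specimens:
            cells = _enh.specimen_enhancements(spec, histogram=histograms)
            for hip, measures in cells.items():
                for (region, sub), m in measures.items():
                    enh_rows.append(
                        {
                            "specimen_id": spec.specimen_id,
                            "hip": hip,
                            "region": region,
                            "subregion": "" if sub is None else sub,
                            "voxel_count": m.voxel_count,
                            "enhancement": m.enhancement,
                        }
                    )
            for cell in TABLE_CELLS:
                estimates.append(
                    _contrib.specimen_contribution(
                        cells["experimental"][cell],
                        cells["control"][cell],
                        spec.infused_artery,
                        specimen_id=spec.specimen_id,
                        floor=self.floor,
                        mode=self.qc,
                    )
                )

        summaries: dict[tuple[str, str | None], dict[str, CohortSummary]] = {}
        for cell in TABLE_CELLS:
            summaries[cell] = {
                artery: _contrib.aggregate_cohort(estimates, cell[0], cell[1], artery)
                for artery in ("MFCA", "LFCA")
            }
        test_results = _stats.compare_regions(estimates) if tests else None
        table = build_table(summaries, test_results)
        return ArterialContributionResults(
            model=self,
            enhancements=pd.DataFrame(enh_rows),
            estimates=estimates,
            summaries=summaries,
            tests=test_results,
            table=table,
        )


@dataclass
class ArterialContributionResults:
    """Fitted results: per-specimen estimates, cohort summaries, tests and
    the 15-row report table."""

    model: ArterialContributionModel
    enhancements: pd.DataFrame
    estimates: list[ContributionEstimate]
    summaries: dict[tuple[str, str | None], dict[str, CohortSummary]]
    tests: dict[tuple[str, str | None], TestResult] | None
    table: pd.DataFrame

    @property
    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": e.specimen_id,
                "region": e.region,
                "subregion": "" if e.subregion is None else e.subregion,
                "mfca_pct": e.mfca_pct,
                "lfca_pct": e.lfca_pct,
                "qc_flag": e.qc_flag,
            }
            for e in self.estimates
        )

    def summary(self) -> str:
        """Aligned-text report table (one row per region/subregion cell)."""
        n = self.summaries[TABLE_CELLS[0]]["MFCA"].n
        head = (
            f"Relative arterial contributions (MFCA vs LFCA), n = {n} specimens\n"
        )
        return head + format_table(self.table)

    def recovery(self, truth_table: pd.DataFrame | None = None) -> RecoveryReport:
        """Compare cohort-mean estimates against cohort-mean simulated truth."""
        from .pipeline import truth_comparison

        truth = truth_table if truth_table is not None else self.model.truth_table
        if truth is None:
            raise ValidationError("no truth table available; run from_simulation or pass one")
        return truth_comparison(self, truth)

    def save(self, out_dir) -> dict[str, Path]:
        """Write enhancement, estimate and summary tables (CSV + text)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "enhancements": out / "enhancements.csv",
            "contributions": out / "contributions.csv",
            "summary_csv": out / "summary.csv",
            "summary_txt": out / "summary.txt",
        }
        self.enhancements.to_csv(paths["enhancements"], index=False)
        self.estimates_frame.to_csv(paths["contributions"], index=False)
        self.table.to_csv(paths["summary_csv"], index=False)
        paths["summary_txt"].write_text(self.summary() + "\n")
        return paths

    def plot_contributions(self, ax=None):
        """Bar chart of cohort-mean MFCA% per cell with SD error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4.5))
        cells = [cell_name(r, s) for r, s in TABLE_CELLS]
        means = [self.summaries[c]["MFCA"].mean for c in TABLE_CELLS]
        sds = [self.summaries[c]["MFCA"].sd for c in TABLE_CELLS]
        x = np.arange(len(cells))
        ax.bar(x, means, yerr=sds, capsize=3, color="#88619e")
        ax.axhline(50.0, color="0.4", lw=0.8, ls="--")
        ax.set_xticks(x)
        ax.set_xticklabels(cells, rotation=60, ha="right", fontsize=8)
        ax.set_ylabel("MFCA contribution (%)")
        ax.set_ylim(0, 100)
        ax.figure.tight_layout()
        return ax
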