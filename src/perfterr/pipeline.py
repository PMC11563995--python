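"""End-to-end orchestration: simulate or analyze, then report.

``run_pipeline`` drives the full flow (phantom generation or manifest
loading -> enhancement -> contribution -> statistics -> report files) from a
:class:`RunConfig`, with one root seed, a config echo in the run log, and —
in simulate mode — a truth table and truth-vs-estimate recovery report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .contribution import DEFAULT_CONTROL_FLOOR
from .errors import ValidationError
from .model import ArterialContributionModel, ArterialContributionResults, RecoveryReport
from .phantom import CohortConfig, PhantomConfig, generate_cohort
from .regions import BONE_SUBREGION_CELLS, TABLE_CELLS

__all__ = ["RunConfig", "run_pipeline", "truth_comparison", "cohort_config_from_yaml"]

log = logging.getLogger("perfterr")


@dataclass
class RunConfig:
    """One pipeline run: either simulate a cohort or analyze manifests."""

    mode: str  # "simulate" | "analyze"
    out_dir: str
    seed: int = 0
    cohort: CohortConfig | None = None
    manifests: list[str] = field(default_factory=list)
    qc: str = "strict"
    floor: float = DEFAULT_CONTROL_FLOOR
    log_level: str = "INFO"
    write_volumes: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValidationError(f"mode must be simulate|analyze, got {self.mode!r}")
        if self.mode == "simulate" and self.manifests:
            raise ValidationError("simulate mode takes a cohort config, not manifests")
        if self.mode == "analyze" and not self.manifests:
            raise ValidationError("analyze mode requires at least one specimen manifest")
        if self.mode == "simulate" and self.cohort is None:
            self.cohort = CohortConfig()


def _cell_key(region: str, subregion: str | None) -> tuple[str, str]:
    return region, "" if subregion is None else subregion


def truth_comparison(
    results: ArterialContributionResults, truth_table: pd.DataFrame
) -> RecoveryReport:
    """Per-cell absolute error between the cohort-mean MFCA% estimate and the
    cohort-mean simulated truth, plus the overall MAE (percentage points)."""
    est = results.estimates_frame
    est_ids = set(est["specimen_id"])
    truth_ids = set(truth_table["specimen_id"])
    if est_ids != truth_ids:
        raise ValidationError(
            f"specimen ids differ between estimates and truth table: "
            f"only-estimates={sorted(est_ids - truth_ids)}, "
            f"only-truth={sorted(truth_ids - est_ids)}"
        )
    truth = truth_table.copy()
    truth["subregion"] = truth["subregion"].fillna("")
    rows = []
    for region, sub in TABLE_CELLS:
        r, s = _cell_key(region, sub)
        est_mean = est.loc[
            (est["region"] == r) & (est["subregion"] == s) & (est["qc_flag"] == "ok"),
            "mfca_pct",
        ].mean()
        cell_truth = truth.loc[
            (truth["region"] == r) & (truth["subregion"] == s), "mfca_fraction"
        ]
        if cell_truth.empty:
            raise ValidationError(f"truth table has no rows for cell ({r}, {s or None})")
        truth_mean = 100.0 * cell_truth.mean()
        rows.append(
            {
                "region": r,
                "subregion": s,
                "estimate_mean_pct": float(est_mean),
                "truth_mean_pct": float(truth_mean),
                "abs_error_pp": abs(float(est_mean) - float(truth_mean)),
            }
        )
    table = pd.DataFrame(rows)
    return RecoveryReport(table=table, mae=float(table["abs_error_pp"].mean()))


def run_pipeline(config: RunConfig) -> ArterialContributionResults:
    """Execute one run and write the report bundle under ``config.out_dir``.

    Outputs: enhancements.csv, contributions.csv, summary.csv, summary.txt,
    run.json (config echo + seed); in simulate mode additionally the phantom
    volumes/manifests (unless ``write_volumes=False``), truth_table.csv and
    recovery.csv.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth_table = None
    if config.mode == "simulate":
        log.info("simulating cohort of %d specimens (seed=%d)",
                 config.cohort.n_specimens, config.seed)
        dataset, truth_table = generate_cohort(config.cohort, config.seed)
        if config.write_volumes:
            _io.write_cohort(dataset, truth_table, out / "data")
        model = ArterialContributionModel(dataset.specimens, floor=config.floor, qc=config.qc)
        model.truth_table = truth_table
    else:
        log.info("loading %d specimen manifests", len(config.manifests))
        model = ArterialContributionModel.from_manifests(
            config.manifests, floor=config.floor, qc=config.qc
        )

    current_stage = "quantify"
    try:
        results = model.fit()
        current_stage = "report"
        results.save(out)
        run_echo = {
            "mode": config.mode,
            "seed": config.seed,
            "qc": config.qc,
            "floor": config.floor,
            "n_specimens": len(model.specimens),
            "cohort": _cohort_echo(config.cohort) if config.cohort else None,
            "manifests": list(config.manifests),
        }
        (out / "run.json").write_text(json.dumps(run_echo, indent=2))
        if truth_table is not None:
            truth_table.to_csv(out / "truth_table.csv", index=False)
            current_stage = "truth_comparison"
            report = truth_comparison(results, truth_table)
            report.table.to_csv(out / "recovery.csv", index=False)
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{current_stage}' failed: {exc}") from exc
    log.info("run complete; report written to %s", out)
    return results


def _cohort_echo(cohort: CohortConfig) -> dict:
    return {
        "n_specimens": cohort.n_specimens,
        "allocation": cohort.allocation,
        "within_region_jitter_sd": cohort.within_region_jitter_sd,
        "truth_means": {f"{r}/{s}": v for (r, s), v in cohort.truth_means.items()},
        "truth_sds": {f"{r}/{s}": v for (r, s), v in cohort.truth_sds.items()},
        "phantom": {
            "grid_shape": list(cohort.phantom.grid_shape),
            "voxel_spacing": list(cohort.phantom.voxel_spacing),
            "baseline_signal": cohort.phantom.baseline_signal,
            "muscle_signal": cohort.phantom.muscle_signal,
            "enhancement_amplitude": cohort.phantom.enhancement_amplitude,
            "noise_sd": cohort.phantom.noise_sd,
            "noise_model": cohort.phantom.noise_model,
        },
    }


def cohort_config_from_yaml(path) -> CohortConfig:
    """Parse a cohort configuration from YAML with schema validation.

    Expected layout::

        n_specimens: 10
        allocation: balanced
        within_region_jitter_sd: 0.05
        truth:
          ST: {anterior: {mean: 0.808, sd: 0.212}, posterior: {...}}
          ...
        phantom:
          grid_shape: [64, 48, 80]
          noise_sd: 5.0
          ...
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: cohort config must be a YAML mapping")
    allowed = {"n_specimens", "allocation", "within_region_jitter_sd", "truth", "phantom"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(f"{path}: unknown cohort config keys {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("n_specimens", "allocation", "within_region_jitter_sd"):
        if key in raw:
            kwargs[key] = raw[key]
    if "truth" in raw:
        means, sds = {}, {}
        for region, subs in raw["truth"].items():
            for sub, params in subs.items():
                if not isinstance(params, dict) or not {"mean", "sd"} <= set(params):
                    raise ValidationError(
                        f"{path}: truth.{region}.{sub} must provide 'mean' and 'sd'"
                    )
                means[(region, sub)] = float(params["mean"])
                sds[(region, sub)] = float(params["sd"])
        missing = [c for c in BONE_SUBREGION_CELLS if c not in means]
        if missing:
            raise ValidationError(f"{path}: truth block missing cells {missing}")
        kwargs["truth_means"] = means
        kwargs["truth_sds"] = sds
    if "phantom" in raw:
        pk = dict(raw["phantom"])
        unknown = set(pk) - {
            "grid_shape", "voxel_spacing", "baseline_signal", "muscle_signal",
            "enhancement_amplitude", "noise_sd", "noise_model", "seed",
        }
        if unknown:
            raise ValidationError(f"{path}: unknown phantom keys {sorted(unknown)}")
        for tup_key in ("grid_shape", "voxel_spacing"):
            if tup_key in pk:
                pk[tup_key] = tuple(pk[tup_key])
        kwargs["phantom"] = PhantomConfig(**pk)
    return CohortConfig(**kwargs)
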