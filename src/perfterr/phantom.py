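"""Synthetic paired-hip contrast-MRI phantom generator.

Emulates the cadaveric study design this package analyses: each specimen has
one *experimental* hip whose single infused artery (MFCA or LFCA) received
contrast, and one *control* hip in which both arteries were infused with
equal doses, so the control enhancement represents the total (MFCA + LFCA)
supply. Geometry is schematic — labeled rectangular blocks for the four
trochanteric regions and a muscle reference — because the downstream
analysis consumes only masks and intensities.

The generator is linear in infusion: a post-contrast bone voxel gains

    enhancement_amplitude * (w_M * I_M + (1 - w_M) * I_L)

where ``w_M`` is the voxel's MFCA territory weight (the per-subregion truth
fraction plus an optional smooth jitter field, clipped to [0, 1]) and
``I_M``, ``I_L`` are 0/1 infusion indicators (both 1 on the control hip).
Muscle never enhances. Fat suppression is modeled as a low flat trabecular
baseline. Noise is additive Gaussian by default; a Rician option models
magnitude-MRI noise at low SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .errors import GridError, ValidationError
from .regions import (
    ARTERIES,
    BONE_SUBREGION_CELLS,
    CANONICAL_LABELS,
    FULL,
    MUSCLE_LABEL,
    REGIONS,
    SIDES,
    SUBREGIONS,
    TABLE_CELLS,
)
from .volumes import ROIMaskSet, SpecimenImageSet, Volume3D

__all__ = [
    "PhantomConfig",
    "TerritoryTruth",
    "ExperimentAssignment",
    "CohortConfig",
    "CohortDataset",
    "DEFAULT_TRUTH_MEANS",
    "DEFAULT_TRUTH_SDS",
    "region_masks",
    "build_specimen_phantom",
    "draw_cohort_truths",
    "generate_cohort",
    "clipped_normal_mean",
]

#: Default between-specimen mean MFCA fraction per (region, subregion),
#: the study conditions the cohort generator emulates.
DEFAULT_TRUTH_MEANS: dict[tuple[str, str], float] = {
    ("ST", "anterior"): 0.808,
    ("ST", "posterior"): 0.711,
    ("LT", "anterior"): 0.700,
    ("LT", "posterior"): 0.728,
    ("IT", "anterior"): 0.700,
    ("IT", "posterior"): 0.780,
    ("GT", "anterior"): 0.503,
    ("GT", "posterior"): 0.548,
}

#: Default between-specimen SD of the MFCA fraction per (region, subregion).
DEFAULT_TRUTH_SDS: dict[tuple[str, str], float] = {
    ("ST", "anterior"): 0.212,
    ("ST", "posterior"): 0.351,
    ("LT", "anterior"): 0.385,
    ("LT", "posterior"): 0.385,
    ("IT", "anterior"): 0.316,
    ("IT", "posterior"): 0.293,
    ("GT", "anterior"): 0.361,
    ("GT", "posterior"): 0.367,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, signal and noise parameters of one synthetic specimen.

    ``voxel_spacing`` is mm per axis (x, y, z); the y spacing is the coronal
    slice thickness, default 2 mm. Signal levels are arbitrary intensity
    units; defaults put the analysis in the high-SNR regime of fat-suppressed
    post-contrast imaging (baseline 100, amplitude 150, noise SD 5).
    """

    grid_shape: tuple[int, int, int] = (64, 48, 80)
    voxel_spacing: tuple[float, float, float] = (1.0, 2.0, 1.0)
    baseline_signal: float = 100.0
    muscle_signal: float = 100.0
    enhancement_amplitude: float = 150.0
    noise_sd: float = 5.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValidationError(f"grid_shape must be 3 axes all >= 8, got {self.grid_shape}")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if self.enhancement_amplitude <= 0:
            raise ValidationError("enhancement_amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValidationError(f"noise_model must be gaussian|rician, got {self.noise_model!r}")
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "voxel_spacing", tuple(float(s) for s in self.voxel_spacing))


@dataclass(frozen=True)
class TerritoryTruth:
    """Ground-truth MFCA territory fractions for one specimen.

    ``mfca_fraction`` maps each of the eight (region, subregion) cells to the
    fraction of that cell's supply coming from the MFCA. A smooth random
    field with SD ``within_region_jitter_sd`` (fraction units) is added per
    voxel and clipped to [0, 1], modeling within-region heterogeneity.
    """

    mfca_fraction: Mapping[tuple[str, str], float]
    within_region_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        fracs = {(str(r), str(s)): float(v) for (r, s), v in dict(self.mfca_fraction).items()}
        missing = [c for c in BONE_SUBREGION_CELLS if c not in fracs]
        if missing:
            raise ValidationError(f"missing territory fractions for cells {missing}")
        bad = {c: v for c, v in fracs.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValidationError(f"territory fractions outside [0, 1]: {bad}")
        if self.within_region_jitter_sd < 0:
            raise ValidationError("within_region_jitter_sd must be >= 0")
        object.__setattr__(self, "mfca_fraction", fracs)

    @classmethod
    def uniform(cls, fraction: float, jitter_sd: float = 0.0) -> "TerritoryTruth":
        """Same MFCA fraction in every subregion."""
        return cls({c: fraction for c in BONE_SUBREGION_CELLS}, jitter_sd)


@dataclass(frozen=True)
class ExperimentAssignment:
    """Which hip is experimental and which single artery it received."""

    experimental_side: str = "left"
    infused_artery: str = "MFCA"

    def __post_init__(self) -> None:
        if self.experimental_side not in SIDES:
            raise ValidationError(f"experimental_side must be one of {SIDES}")
        if self.infused_artery not in ARTERIES:
            raise ValidationError(f"infused_artery must be one of {ARTERIES}")


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration: cohort size, randomization and the
    between-specimen truth distribution (clipped normal per subregion)."""

    n_specimens: int = 10
    allocation: str = "balanced"
    truth_means: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_MEANS)
    )
    truth_sds: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_SDS)
    )
    within_region_jitter_sd: float = 0.05
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise ValidationError("n_specimens must be >= 2")
        if self.allocation not in ("balanced", "bernoulli"):
            raise ValidationError(f"allocation must be balanced|bernoulli, got {self.allocation!r}")
        means = {(str(r), str(s)): float(v) for (r, s), v in dict(self.truth_means).items()}
        sds = {(str(r), str(s)): float(v) for (r, s), v in dict(self.truth_sds).items()}
        for table, name in ((means, "truth_means"), (sds, "truth_sds")):
            missing = [c for c in BONE_SUBREGION_CELLS if c not in table]
            if missing:
                raise ValidationError(f"{name} missing cells {missing}")
        if any(not 0.0 <= v <= 1.0 for v in means.values()):
            raise ValidationError("truth means must lie in [0, 1]")
        if any(v < 0 for v in sds.values()):
            raise ValidationError("truth SDs must be >= 0")
        if self.within_region_jitter_sd < 0:
            raise ValidationError("within_region_jitter_sd must be >= 0")
        object.__setattr__(self, "truth_means", means)
        object.__setattr__(self, "truth_sds", sds)


@dataclass
class CohortDataset:
    """A generated cohort: the specimens plus the configuration that made it."""

    specimens: list[SpecimenImageSet]
    config: CohortConfig
    seed: int

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self):
        return iter(self.specimens)


# Block layout as fractions of the grid per axis. The four bone regions share
# one anterior-posterior band (even voxel count, so the halves are equal); the
# muscle reference sits medially, disjoint from bone.
_BONE_Y = (0.15, 0.85)
_BLOCKS = {
    "ST": {"x": (0.30, 0.70), "z": (0.05, 0.30)},
    "LT": {"x": (0.12, 0.38), "z": (0.35, 0.55)},
    "IT": {"x": (0.45, 0.75), "z": (0.35, 0.70)},
    "GT": {"x": (0.60, 0.90), "z": (0.75, 0.95)},
}
_MUSCLE = {"x": (0.00, 0.08), "y": (0.10, 0.90), "z": (0.05, 0.95)}

_LABEL_OF = {v: k for k, v in CANONICAL_LABELS.items()}
_masks_cache: dict[tuple, ROIMaskSet] = {}


def _span(lo: float, hi: float, n: int) -> tuple[int, int]:
    return int(round(lo * n)), int(round(hi * n))


def region_masks(config: PhantomConfig) -> ROIMaskSet:
    """Build the schematic proximal-femur label volume for a grid.

    GT is a superolateral block, LT a medial mid-level block, IT the band
    between them and ST an inferior band; each region is split into
    anterior/posterior halves at its y-midplane. Raises :class:`GridError`
    if any region (or either half) would be empty on this grid.
    """
    key = (config.grid_shape, config.voxel_spacing)
    cached = _masks_cache.get(key)
    if cached is not None:
        return cached

    nx, ny, nz = config.grid_shape
    labels = np.zeros(config.grid_shape, dtype=np.int16)

    y0, y1 = _span(*_BONE_Y, ny)
    y1 = y0 + 2 * ((y1 - y0) // 2)  # even extent -> equal ant/post halves
    ymid = (y0 + y1) // 2
    if y1 - y0 < 2:
        raise GridError(f"grid {config.grid_shape} too small: bone y band empty")

    for region, spans in _BLOCKS.items():
        x0, x1 = _span(*spans["x"], nx)
        z0, z1 = _span(*spans["z"], nz)
        if x0 >= x1 or z0 >= z1:
            raise GridError(f"grid {config.grid_shape} too small to host region {region}")
        if np.any(labels[x0:x1, y0:ymid, z0:z1]) or np.any(labels[x0:x1, ymid:y1, z0:z1]):
            raise GridError(f"grid {config.grid_shape}: region {region} overlaps another region")
        labels[x0:x1, y0:ymid, z0:z1] = _LABEL_OF[(region, "anterior")]
        labels[x0:x1, ymid:y1, z0:z1] = _LABEL_OF[(region, "posterior")]

    mx0, mx1 = _span(*_MUSCLE["x"], nx)
    my0, my1 = _span(*_MUSCLE["y"], ny)
    mz0, mz1 = _span(*_MUSCLE["z"], nz)
    if mx0 >= mx1 or my0 >= my1 or mz0 >= mz1:
        raise GridError(f"grid {config.grid_shape} too small to host the muscle reference")
    if np.any(labels[mx0:mx1, my0:my1, mz0:mz1]):
        raise GridError(f"grid {config.grid_shape}: muscle block overlaps bone")
    labels[mx0:mx1, my0:my1, mz0:mz1] = MUSCLE_LABEL

    masks = ROIMaskSet(labels, dict(CANONICAL_LABELS))
    masks.validate()
    _masks_cache[key] = masks
    return masks


def _territory_weights(
    masks: ROIMaskSet, truth: TerritoryTruth, rng: np.random.Generator
) -> np.ndarray:
    """Per-voxel MFCA weight field: subregion fraction + smooth jitter, clipped."""
    w = np.zeros(masks.shape, dtype=np.float64)
    for cell in BONE_SUBREGION_CELLS:
        w[masks.labels == _LABEL_OF[cell]] = truth.mfca_fraction[cell]
    if truth.within_region_jitter_sd > 0:
        field_ = gaussian_filter(rng.standard_normal(masks.shape), sigma=2.0)
        sd = field_.std()
        if sd > 0:
            field_ /= sd
        w += truth.within_region_jitter_sd * field_
        np.clip(w, 0.0, 1.0, out=w)
    return w


def _add_noise(clean: np.ndarray, config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_sd == 0:
        return clean.copy()
    if config.noise_model == "gaussian":
        return clean + rng.normal(0.0, config.noise_sd, clean.shape)
    # Rician: magnitude of a complex signal with iid Gaussian channel noise.
    re = clean + rng.normal(0.0, config.noise_sd, clean.shape)
    im = rng.normal(0.0, config.noise_sd, clean.shape)
    return np.hypot(re, im)


def realized_truth_table(
    masks: ROIMaskSet, weights: np.ndarray
) -> dict[tuple[str, str | None], float]:
    """Voxel-averaged MFCA fraction per report cell, from the weight field."""
    out: dict[tuple[str, str | None], float] = {}
    for region, sub in TABLE_CELLS:
        m = masks.mask(region, sub)
        out[(region, sub)] = float(weights[m].mean())
    return out


def build_specimen_phantom(
    config: PhantomConfig,
    truth: TerritoryTruth,
    assignment: ExperimentAssignment,
    seed: int | None = None,
    specimen_id: str = "phantom",
) -> SpecimenImageSet:
    """Generate the four volumes (pre/post x experimental/control hip) of one
    specimen, with the realized per-cell truth attached.

    The control hip is dual-infused (both indicators 1), so its bone
    enhancement equals ``enhancement_amplitude`` everywhere; the experimental
    hip enhances by ``amplitude * w`` (MFCA infused) or ``amplitude * (1-w)``
    (LFCA infused). The same territory field serves both hips — the paired
    hips of one donor share one vascular anatomy.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    masks = region_masks(config)
    weights = _territory_weights(masks, truth, rng)
    bone = masks.mask(FULL)
    muscle = masks.muscle_mask()

    pre_clean = np.zeros(config.grid_shape, dtype=np.float64)
    pre_clean[bone] = config.baseline_signal
    pre_clean[muscle] = config.muscle_signal

    if assignment.infused_artery == "MFCA":
        exp_gain = weights
    else:
        exp_gain = 1.0 - weights
    post_exp_clean = pre_clean + config.enhancement_amplitude * exp_gain * bone
    post_ctrl_clean = pre_clean + config.enhancement_amplitude * bone

    volumes = [
        _add_noise(pre_clean, config, rng),
        _add_noise(post_exp_clean, config, rng),
        _add_noise(pre_clean, config, rng),
        _add_noise(post_ctrl_clean, config, rng),
    ]
    vols = [Volume3D(v, config.voxel_spacing) for v in volumes]
    return SpecimenImageSet(
        specimen_id=specimen_id,
        pre_experimental=vols[0],
        post_experimental=vols[1],
        pre_control=vols[2],
        post_control=vols[3],
        masks_experimental=masks,
        masks_control=masks,
        experimental_side=assignment.experimental_side,
        infused_artery=assignment.infused_artery,
        truth=realized_truth_table(masks, weights),
    )


def clipped_normal_mean(mu: float, sd: float) -> float:
    """Mean of clip(N(mu, sd), 0, 1) in closed form.

    E[clip(X)] = mu + sd*(phi(a) - phi(b)) + (0 - mu)*Phi(a) + (1 - mu)*(1 - Phi(b))
    with a = -mu/sd, b = (1-mu)/sd. Used to state the truth-draw mean
    invariant exactly under clipping.
    """
    if sd == 0:
        return float(np.clip(mu, 0.0, 1.0))
    a = (0.0 - mu) / sd
    b = (1.0 - mu) / sd
    return float(
        mu
        + sd * (norm.pdf(a) - norm.pdf(b))
        - mu * norm.cdf(a)
        + (1.0 - mu) * norm.sf(b)
    )


def draw_cohort_truths(cohort: CohortConfig, seed: int) -> list[TerritoryTruth]:
    """Draw per-specimen territory truths from the configured clipped-normal
    distribution (one independent draw per subregion)."""
    rng = np.random.default_rng(seed)
    truths = []
    for _ in range(cohort.n_specimens):
        fracs = {
            cell: float(
                np.clip(rng.normal(cohort.truth_means[cell], cohort.truth_sds[cell]), 0.0, 1.0)
            )
            for cell in BONE_SUBREGION_CELLS
        }
        truths.append(TerritoryTruth(fracs, cohort.within_region_jitter_sd))
    return truths


def _draw_assignments(cohort: CohortConfig, rng: np.random.Generator) -> list[ExperimentAssignment]:
    n = cohort.n_specimens
    if cohort.allocation == "balanced":
        arteries = ["MFCA"] * (n // 2) + ["LFCA"] * (n // 2)
        if n % 2:
            arteries.append(str(rng.choice(ARTERIES)))
        arteries = [arteries[i] for i in rng.permutation(n)]
    else:
        arteries = [str(rng.choice(ARTERIES)) for _ in range(n)]
    sides = [str(rng.choice(SIDES)) for _ in range(n)]
    return [ExperimentAssignment(s, a) for s, a in zip(sides, arteries)]


def generate_cohort(cohort: CohortConfig, seed: int):
    """Generate a reproducible cohort of paired-hip phantom specimens.

    Returns ``(dataset, truth_table)`` where ``truth_table`` is a pandas
    DataFrame of realized per-cell MFCA fractions (one row per specimen and
    report cell). All randomness flows from ``seed`` via per-specimen
    substreams, so the same seed yields bitwise-identical datasets.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    specimen_seeds = rng.integers(0, 2**31, size=cohort.n_specimens)
    truths = draw_cohort_truths(cohort, int(rng.integers(0, 2**31)))
    assignments = _draw_assignments(cohort, rng)

    specimens = []
    rows = []
    for i, (truth, assignment) in enumerate(zip(truths, assignments)):
        sid = f"S{i + 1:03d}"
        spec = build_specimen_phantom(
            cohort.phantom, truth, assignment, seed=int(specimen_seeds[i]), specimen_id=sid
        )
        specimens.append(spec)
        for (region, sub), frac in spec.truth.items():
            rows.append(
                {
                    "specimen_id": sid,
                    "region": region,
                    "subregion": "" if sub is None else sub,
                    "mfca_fraction": frac,
                    "infused_artery": assignment.infused_artery,
                    "experimental_side": assignment.experimental_side,
                }
            )
    truth_table = pd.DataFrame(rows)
    return CohortDataset(specimens, cohort, seed), truth_table


def noise_free(config: PhantomConfig) -> PhantomConfig:
    """Copy of ``config`` with noise switched off."""
    return replace(config, noise_sd=0.0)
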