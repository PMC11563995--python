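"""Core in-memory containers: intensity volumes, labeled ROI masks, and the
four-scan specimen image set.

Axis convention (fixed package-wide): axis 0 = x (medial->lateral),
axis 1 = y (anterior->posterior; the coronal slice index), axis 2 = z
(inferior->superior). Voxel indices are 0-based with half-open ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import CongruenceError, DimensionalityError, ValidationError
from .regions import (
    ARTERIES,
    BACKGROUND_LABEL,
    FULL,
    MUSCLE,
    REGIONS,
    SIDES,
    SUBREGIONS,
)


@dataclass(frozen=True)
class Volume3D:
    """A 3-D scalar intensity grid with physical voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"volume must be 3-D, got {data.ndim}-D with shape {data.shape}"
            )
        n_bad = int(np.size(data) - np.isfinite(data).sum())
        if n_bad:
            raise ValidationError(f"volume contains {n_bad} non-finite voxel(s)")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def scaled(self, factor: float) -> "Volume3D":
        """Return a copy with all intensities multiplied by ``factor``."""
        return Volume3D(self.data * factor, self.spacing)


@dataclass(frozen=True)
class ROIMaskSet:
    """Integer-labeled ROI volume plus the label -> (region, subregion) map."""

    labels: np.ndarray
    label_map: Mapping[int, tuple[str, str | None]]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise DimensionalityError(
                f"label grid must be 3-D, got {labels.ndim}-D with shape {labels.shape}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError(f"label grid must be integer-typed, got {labels.dtype}")
        label_map = {int(k): (str(v[0]), None if v[1] is None else str(v[1]))
                     for k, v in dict(self.label_map).items()}
        present = set(np.unique(labels).tolist()) - {BACKGROUND_LABEL}
        unknown = present - set(label_map)
        if unknown:
            raise ValidationError(f"labels {sorted(unknown)} missing from label map")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "label_map", label_map)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def labels_for(self, region: str, subregion: str | None = None) -> list[int]:
        """Labels belonging to a region (``FULL`` = all four bone regions),
        optionally restricted to one subregion."""
        if region == FULL:
            wanted_regions = set(REGIONS)
        elif region in REGIONS or region == MUSCLE:
            wanted_regions = {region}
        else:
            raise ValueError(f"unknown region {region!r}")
        if subregion is not None and subregion not in SUBREGIONS:
            raise ValueError(f"unknown subregion {subregion!r}")
        return sorted(
            lab
            for lab, (reg, sub) in self.label_map.items()
            if reg in wanted_regions and (subregion is None or sub == subregion)
        )

    def mask(self, region: str, subregion: str | None = None) -> np.ndarray:
        """Boolean voxel mask for a region/subregion cell."""
        labs = self.labels_for(region, subregion)
        return np.isin(self.labels, labs)

    def muscle_mask(self) -> np.ndarray:
        return self.mask(MUSCLE)

    def validate(self) -> None:
        """Check the structural invariants: muscle nonempty, every bone
        region nonempty in both halves."""
        if not self.muscle_mask().any():
            raise ValidationError("muscle reference region is empty")
        for region in REGIONS:
            for sub in SUBREGIONS:
                if not self.mask(region, sub).any():
                    raise ValidationError(f"region {region} {sub} half is empty")


@dataclass
class SpecimenImageSet:
    """The four scans of one specimen (pre/post x experimental/control hip)
    with the two per-hip mask sets and infusion metadata.

    ``truth`` carries, for phantom-generated specimens, the realized
    (voxel-averaged) MFCA territory fraction per report cell.
    """

    specimen_id: str
    pre_experimental: Volume3D
    post_experimental: Volume3D
    pre_control: Volume3D
    post_control: Volume3D
    masks_experimental: ROIMaskSet
    masks_control: ROIMaskSet
    experimental_side: str
    infused_artery: str
    truth: dict[tuple[str, str | None], float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.infused_artery not in ARTERIES:
            raise ValidationError(
                f"infused_artery {self.infused_artery!r} not in {ARTERIES}"
            )
        if self.experimental_side not in SIDES:
            raise ValidationError(
                f"experimental_side {self.experimental_side!r} not in {SIDES}"
            )
        self._check_congruence()
        self.masks_experimental.validate()
        self.masks_control.validate()

    def _check_congruence(self) -> None:
        vols = {
            "pre_experimental": self.pre_experimental,
            "post_experimental": self.post_experimental,
            "pre_control": self.pre_control,
            "post_control": self.post_control,
        }
        ref_name, ref = next(iter(vols.items()))
        for name, vol in vols.items():
            if vol.shape != ref.shape or vol.spacing != ref.spacing:
                raise CongruenceError(
                    f"{name} grid {vol.shape}/{vol.spacing} differs from "
                    f"{ref_name} {ref.shape}/{ref.spacing}"
                )
        for name, masks in (
            ("masks_experimental", self.masks_experimental),
            ("masks_control", self.masks_control),
        ):
            if masks.shape != ref.shape:
                raise CongruenceError(
                    f"{name} shape {masks.shape} differs from volumes {ref.shape}"
                )

    def hip(self, which: str) -> tuple[Volume3D, Volume3D, ROIMaskSet]:
        """Return (pre, post, masks) for ``'experimental'`` or ``'control'``."""
        if which == "experimental":
            return self.pre_experimental, self.post_experimental, self.masks_experimental
        if which == "control":
            return self.pre_control, self.post_control, self.masks_control
        raise ValueError(f"hip must be 'experimental' or 'control', got {which!r}")
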