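"""File interfaces: NIfTI-1 volumes and masks, JSON manifests, CSV tables.

The pipeline contract is NIfTI (single file, unambiguous geometry); mask
volumes are integer-labeled NIfTI with a JSON sidecar mapping label ->
(region, subregion). Intensities are stored as 32-bit float. Loading never
mutates files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, DimensionalityError, ManifestError
from .regions import ARTERIES, SIDES
from .volumes import ROIMaskSet, SpecimenImageSet, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_masks",
    "write_masks",
    "SpecimenManifest",
    "read_manifest",
    "write_manifest",
    "load_specimen",
    "write_specimen",
    "write_cohort",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(volume: Volume3D, path) -> None:
    """Write a volume as NIfTI-1 (float32) with spacing in the affine."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path) -> Volume3D:
    """Read a 3-D NIfTI volume; validates dimensionality and finiteness."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except DimensionalityError:
        raise
    except Exception as exc:  # nibabel raises several load-error types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data, dtype=np.float64), spacing)


def write_masks(masks: ROIMaskSet, path, label_map_path=None) -> None:
    """Write the label volume (int16 NIfTI) and its JSON label map."""
    path = Path(path)
    img = nib.Nifti1Image(masks.labels.astype(np.int16), np.eye(4))
    nib.save(img, str(path))
    lm_path = Path(label_map_path) if label_map_path else _label_map_path(path)
    payload = {
        str(lab): {"region": reg, "subregion": sub}
        for lab, (reg, sub) in masks.label_map.items()
    }
    lm_path.write_text(json.dumps(payload, indent=2))


def _label_map_path(mask_path: Path) -> Path:
    name = mask_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return mask_path.with_name(name[: -len(suffix)] + ".labels.json")
    return mask_path.with_suffix(".labels.json")


def read_masks(path, label_map_path=None) -> ROIMaskSet:
    path = Path(path)
    try:
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if labels.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3-D label image, got {labels.ndim}-D")
    lm_path = Path(label_map_path) if label_map_path else _label_map_path(path)
    if not lm_path.exists():
        raise ManifestError(f"label map {lm_path} not found for mask {path}")
    raw = json.loads(lm_path.read_text())
    label_map = {
        int(k): (str(v["region"]), v.get("subregion")) for k, v in raw.items()
    }
    return ROIMaskSet(np.asarray(np.rint(labels), dtype=np.int16), label_map)


_VOLUME_KEYS = ("pre_experimental", "post_experimental", "pre_control", "post_control")
_MASK_KEYS = ("masks_experimental", "masks_control")


@dataclass(frozen=True)
class SpecimenManifest:
    """Paths to one specimen's four scans and two mask sets, plus the
    randomization metadata (experimental side, infused artery)."""

    specimen_id: str
    pre_experimental: str
    post_experimental: str
    pre_control: str
    post_control: str
    masks_experimental: str
    masks_control: str
    experimental_side: str
    infused_artery: str

    def __post_init__(self) -> None:
        if self.infused_artery not in ARTERIES:
            raise ManifestError(
                f"infused_artery {self.infused_artery!r} invalid; allowed values: "
                f"{', '.join(ARTERIES)}"
            )
        if self.experimental_side not in SIDES:
            raise ManifestError(
                f"experimental_side {self.experimental_side!r} invalid; allowed values: "
                f"{', '.join(SIDES)}"
            )

    def paths(self) -> dict[str, Path]:
        return {k: Path(getattr(self, k)) for k in _VOLUME_KEYS + _MASK_KEYS}


def read_manifest(path) -> SpecimenManifest:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ManifestError(f"{path}:{exc.lineno}: invalid JSON ({exc.msg})") from exc
    required = ("specimen_id", "experimental_side", "infused_artery") + _VOLUME_KEYS + _MASK_KEYS
    missing = [k for k in required if k not in raw]
    if missing:
        raise ManifestError(f"{path}: missing manifest keys {missing}")
    fields = {k: raw[k] for k in required}
    manifest = SpecimenManifest(**fields)
    base = path.parent
    for key, p in manifest.paths().items():
        full = p if p.is_absolute() else base / p
        if not full.exists():
            raise ManifestError(f"{path}: {key} file {full} does not exist")
    return manifest


def write_manifest(manifest: SpecimenManifest, path) -> None:
    payload = {
        "specimen_id": manifest.specimen_id,
        "experimental_side": manifest.experimental_side,
        "infused_artery": manifest.infused_artery,
        **{k: getattr(manifest, k) for k in _VOLUME_KEYS + _MASK_KEYS},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_specimen(manifest: SpecimenManifest, base_dir=None) -> SpecimenImageSet:
    """Load all four volumes and both mask sets; grid congruence and mask
    completeness are validated by :class:`SpecimenImageSet`."""
    base = Path(base_dir) if base_dir else Path(".")

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    vols = {k: read_volume(resolve(getattr(manifest, k))) for k in _VOLUME_KEYS}
    masks = {k: read_masks(resolve(getattr(manifest, k))) for k in _MASK_KEYS}
    return SpecimenImageSet(
        specimen_id=manifest.specimen_id,
        **vols,
        **masks,
        experimental_side=manifest.experimental_side,
        infused_artery=manifest.infused_artery,
    )


def write_specimen(spec: SpecimenImageSet, out_dir) -> SpecimenManifest:
    """Write one specimen's volumes, masks and manifest under ``out_dir``;
    returns the manifest (with paths relative to ``out_dir``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = spec.specimen_id
    rel = {}
    for key in _VOLUME_KEYS:
        rel[key] = f"{sid}_{key}.nii.gz"
        write_volume(getattr(spec, key), out / rel[key])
    for key in _MASK_KEYS:
        rel[key] = f"{sid}_{key}.nii.gz"
        write_masks(getattr(spec, key), out / rel[key])
    manifest = SpecimenManifest(
        specimen_id=sid,
        experimental_side=spec.experimental_side,
        infused_artery=spec.infused_artery,
        **rel,
    )
    write_manifest(manifest, out / f"{sid}_manifest.json")
    return manifest


def write_cohort(dataset, truth_table: pd.DataFrame, out_dir) -> list[Path]:
    """Write every specimen plus a cohort manifest (JSON) and truth table
    (CSV). Returns the per-specimen manifest paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_paths = []
    for spec in dataset:
        write_specimen(spec, out)
        manifest_paths.append(out / f"{spec.specimen_id}_manifest.json")
    cohort_manifest = {
        "n_specimens": len(dataset.specimens),
        "seed": dataset.seed,
        "specimen_manifests": [p.name for p in manifest_paths],
    }
    (out / "cohort_manifest.json").write_text(json.dumps(cohort_manifest, indent=2))
    truth_table.to_csv(out / "truth_table.csv", index=False)
    return manifest_paths
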