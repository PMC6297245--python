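"""Volume, mask, manifest and feature-table I/O with fixed conventions.

Conventions used throughout the package:

* ``ImageVolume.values`` is a 3D float array indexed ``[x, y, z]`` where z is
  the slice axis (z spacing = slice thickness in mm).
* Voxel indices are 0-based; world position = origin + index * spacing.
* Masks are inclusive: a voxel belongs to the lesion iff its stored value > 0.
* Feature tables are CSV with header ``patient_id,label,<feature...>``,
  comma-separated, UTF-8, "." decimal; labels strictly in {0, 1}
  (1 = mutant, 0 = wild-type). Floats are written with ``repr`` precision so
  a write/read roundtrip is lossless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "LesionMask",
    "CohortManifest",
    "FeatureTable",
    "FormatError",
    "AlignmentError",
    "SchemaError",
    "read_volume",
    "write_volume",
    "read_feature_table",
    "write_feature_table",
    "read_manifest",
    "write_manifest",
]

_VOLUME_EXTENSIONS = (".nrrd", ".nhdr", ".nii", ".nii.gz")


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


class AlignmentError(ValueError):
    """Grids that must share a geometry do not."""


class SchemaError(ValueError):
    """A tabular file violates the expected schema."""


@dataclass(frozen=True)
class ImageVolume:
    """3D scalar grid with anisotropic spacing, axes ordered (x, y, z)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("volume must be a non-empty 3D grid")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume values must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive components")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class LesionMask:
    """Binary grid aligned to its paired :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("mask must be a non-empty 3D grid")
        values = (values > 0)
        if not values.any():
            raise ValueError("mask must contain at least one foreground voxel")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.shape != volume.shape:
            raise AlignmentError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


@dataclass
class ManifestEntry:
    patient_id: str
    label: int
    volumes: dict[str, str] = field(default_factory=dict)  # setting -> volume path
    masks: dict[str, str] = field(default_factory=dict)  # setting -> mask path


@dataclass
class CohortManifest:
    """Per-patient labels and per-setting volume/mask paths."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.patient_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise SchemaError("patient_ids must be unique")
        for e in self.entries:
            if e.label not in (0, 1):
                raise SchemaError(f"label of {e.patient_id} must be 0 or 1")

    @property
    def patient_ids(self) -> list[str]:
        return [e.patient_id for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.entries], dtype=int)

    def settings(self) -> list[str]:
        names: list[str] = []
        for e in self.entries:
            for s in e.volumes:
                if s not in names:
                    names.append(s)
        return names


@dataclass
class FeatureTable:
    """Patients x named features matrix with binary labels."""

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            values = values.reshape(len(self.patient_ids), -1)
        labels = np.asarray(self.labels, dtype=int)
        if values.shape[0] != len(self.patient_ids):
            raise SchemaError("row count must equal patient count")
        if values.shape[1] != len(self.feature_names):
            raise SchemaError("column count must equal feature-name count")
        if labels.shape != (len(self.patient_ids),):
            raise SchemaError("one label per patient required")
        if not np.isin(labels, (0, 1)).all():
            raise SchemaError("labels must be strictly in {0, 1}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise SchemaError(
                "non-finite value for patient "
                f"{self.patient_ids[bad[0]]}, feature {self.feature_names[bad[1]]}"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature names must be unique")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise SchemaError("patient ids must be unique")
        self.values = values
        self.labels = labels

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def column(self, feature_name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(feature_name)
        except ValueError:
            raise KeyError(f"feature {feature_name!r} not in table") from None
        return self.values[:, j]

    def rows(self, indices: Sequence[int]) -> "FeatureTable":
        """Row (patient) subset of the table, in the given order."""
        indices = list(indices)
        return FeatureTable(
            patient_ids=[self.patient_ids[i] for i in indices],
            feature_names=list(self.feature_names),
            values=self.values[indices],
            labels=self.labels[indices],
        )

    def subset(self, feature_names: Sequence[str]) -> "FeatureTable":
        """Restrict the table to the given features, in the given order."""
        missing = [f for f in feature_names if f not in self.feature_names]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        idx = [self.feature_names.index(f) for f in feature_names]
        return FeatureTable(
            patient_ids=list(self.patient_ids),
            feature_names=list(feature_names),
            values=self.values[:, idx],
            labels=self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "patient_id", self.patient_ids)
        return frame


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _check_extension(path: str) -> None:
    lower = str(path).lower()
    if not lower.endswith(_VOLUME_EXTENSIONS):
        raise FormatError(
            f"unsupported volume format for {path!r}; expected one of {_VOLUME_EXTENSIONS}"
        )


def _read_sitk(path: str) -> tuple[np.ndarray, tuple, tuple]:
    _check_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        image = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError on malformed files
        raise FormatError(f"could not read {path!r}: {exc}") from exc
    # sitk arrays are indexed [z, y, x]; normalize to [x, y, z]
    array = np.transpose(sitk.GetArrayFromImage(image), (2, 1, 0))
    return array, tuple(image.GetSpacing()), tuple(image.GetOrigin())


def read_volume(path: str, with_mask_path: str | None = None):
    """Read an NRRD or NIfTI-1 volume (and optionally its aligned mask).

    Returns an :class:`ImageVolume`, or an ``(ImageVolume, LesionMask)``
    tuple when *with_mask_path* is given. The slice axis is normalized to
    the last array axis; spacing and origin come from the file header.
    """
    array, spacing, origin = _read_sitk(path)
    volume = ImageVolume(values=array, spacing=spacing, origin=origin)
    if with_mask_path is None:
        return volume
    marray, mspacing, morigin = _read_sitk(with_mask_path)
    if marray.shape != array.shape:
        raise AlignmentError(
            f"mask grid {marray.shape} does not match volume grid {array.shape}"
        )
    mask = LesionMask(values=marray > 0, spacing=mspacing, origin=morigin)
    return volume, mask


def write_volume(volume: ImageVolume | LesionMask, path: str) -> str:
    """Write a volume or mask to NRRD / NIfTI-1; re-readable bit-identically."""
    _check_extension(path)
    values = volume.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    image = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(values, (2, 1, 0))))
    image.SetSpacing(tuple(volume.spacing))
    image.SetOrigin(tuple(volume.origin))
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise IOError(f"cannot write to {path!r}")
    try:
        sitk.WriteImage(image, str(path), useCompression=True)
    except Exception as exc:
        raise IOError(f"could not write {path!r}: {exc}") from exc
    return str(path)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str) -> FeatureTable:
    """Read a feature-table CSV (columns: patient_id, label, features...)."""
    frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    if "patient_id" not in frame.columns:
        raise SchemaError(f"{path!r}: missing 'patient_id' column")
    if "label" not in frame.columns:
        raise SchemaError(f"{path!r}: missing 'label' column")
    labels = frame["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        bad = labels[~np.isin(labels, (0, 1))][0]
        raise SchemaError(f"{path!r}: label value {bad!r} outside {{0, 1}}")
    feature_names = [c for c in frame.columns if c not in ("patient_id", "label")]
    values = np.empty((len(frame), len(feature_names)), dtype=np.float64)
    for j, name in enumerate(feature_names):
        column = pd.to_numeric(frame[name], errors="coerce").to_numpy(dtype=np.float64)
        raw_na = frame[name].isna().to_numpy()
        bad_rows = np.nonzero(np.isnan(column) & ~raw_na)[0]
        if bad_rows.size:
            i = int(bad_rows[0])
            raise SchemaError(
                f"{path!r}: non-numeric value {frame[name].iloc[i]!r} "
                f"at row {i} (patient {frame['patient_id'].iloc[i]}), column {name!r}"
            )
        values[:, j] = column
    return FeatureTable(
        patient_ids=list(frame["patient_id"]),
        feature_names=feature_names,
        values=values,
        labels=labels.astype(int),
    )


def write_feature_table(table: FeatureTable, path: str) -> str:
    """Write a feature table as CSV with repr-roundtrip float precision."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise IOError(f"cannot write to {path!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(["patient_id", "label", *table.feature_names]) + "\n")
        for i, pid in enumerate(table.patient_ids):
            # repr() guarantees a lossless float text roundtrip
            row = [pid, str(int(table.labels[i]))] + [repr(float(v)) for v in table.values[i]]
            fh.write(",".join(row) + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

def write_manifest(manifest: CohortManifest, path: str) -> str:
    """Write a cohort manifest CSV: one row per patient, one column pair per setting."""
    settings = manifest.settings()
    rows = []
    for e in manifest.entries:
        row: dict[str, object] = {"patient_id": e.patient_id, "label": e.label}
        for s in settings:
            row[f"volume_{s}"] = e.volumes.get(s, "")
            row[f"mask_{s}"] = e.masks.get(s, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return str(path)


def read_manifest(path: str, check_paths: bool = True) -> CohortManifest:
    frame = pd.read_csv(path, dtype=str)
    for required in ("patient_id", "label"):
        if required not in frame.columns:
            raise SchemaError(f"{path!r}: missing {required!r} column")
    settings = [c[len("volume_"):] for c in frame.columns if c.startswith("volume_")]
    base = os.path.dirname(os.path.abspath(path))
    entries = []
    for _, row in frame.iterrows():
        volumes, masks = {}, {}
        for s in settings:
            for mapping, column in ((volumes, f"volume_{s}"), (masks, f"mask_{s}")):
                p = row.get(column)
                if isinstance(p, str) and p:
                    if not os.path.isabs(p):
                        p = os.path.join(base, p)
                    if check_paths and not os.path.exists(p):
                        raise FileNotFoundError(f"manifest references missing file {p!r}")
                    mapping[s] = p
        entries.append(
            ManifestEntry(
                patient_id=str(row["patient_id"]),
                label=int(row["label"]),
                volumes=volumes,
                masks=masks,
            )
        )
    return CohortManifest(entries=entries)
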