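"""Volume and feature-table I/O.

CT volumes and segmentation masks are read and written through SimpleITK
in the standard research formats (NIfTI ``.nii``/``.nii.gz``, NRRD
``.nrrd``, MetaImage ``.mha``/``.mhd``).  The in-memory convention is a
``(z, y, x)`` voxel grid with per-axis spacing in mm; HU values are never
rescaled on the way in or out.

Per-nodule feature tables are plain CSV: one row per nodule, the 15
texture/morphology features plus four metadata columns
(``nodule_id``, ``label``, ``calcified``, ``subgroup``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .cohort_params import FEATURE_NAMES, METADATA_COLUMNS
from .errors import CongruenceError, FormatError, MetadataError, ValidationError

SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".nrrd", ".mha", ".mhd")

AXIS_ORDER = "zyx"


@dataclass
class CTVolume:
    """A 3D CT attenuation grid (HU) with physical voxel geometry.

    ``voxels`` is indexed ``[z, y, x]``; ``spacing`` and ``origin`` are in
    mm in the same axis order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError("volume must be a 3D grid with >= 1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be three positive mm values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class NoduleMask:
    """Binary segmentation mask congruent with its CTVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    nodule_id: str = "nodule"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be a 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def check_congruent(self, volume: CTVolume) -> None:
        if self.shape != volume.shape:
            raise CongruenceError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


def _check_extension(path: str) -> None:
    p = str(path).lower()
    if not any(p.endswith(ext) for ext in SUPPORTED_EXTENSIONS):
        raise FormatError(
            f"unsupported volume format for {path!r}; expected one of {SUPPORTED_EXTENSIONS}"
        )


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume, normalising to the (z, y, x) convention.

    SimpleITK reports size and spacing in (x, y, z); its array view is
    already (z, y, x), so spacing/origin are reversed to match.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _check_extension(path)
    image = sitk.ReadImage(path)
    if image.GetDimension() != 3:
        raise FormatError(f"{path!r} is {image.GetDimension()}D; expected a 3D volume")
    spacing_xyz = image.GetSpacing()
    if any(s <= 0 for s in spacing_xyz):
        raise MetadataError(f"non-positive spacing {spacing_xyz} in {path!r}")
    arr = sitk.GetArrayFromImage(image)  # (z, y, x)
    return CTVolume(
        voxels=arr,
        spacing=tuple(reversed(spacing_xyz)),
        origin=tuple(reversed(image.GetOrigin())),
    )


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a CTVolume; integer HU grids round-trip bit-faithfully."""
    path = os.fspath(path)
    _check_extension(path)
    image = sitk.GetImageFromArray(volume.voxels)
    image.SetSpacing(tuple(reversed(volume.spacing)))
    image.SetOrigin(tuple(reversed(volume.origin)))
    sitk.WriteImage(image, path)


def read_mask(path: str | os.PathLike, nodule_id: str | None = None) -> NoduleMask:
    vol = read_volume(path)
    if nodule_id is None:
        nodule_id = _nodule_id_from_path(path)
    return NoduleMask(
        voxels=vol.voxels > 0, spacing=vol.spacing, nodule_id=nodule_id, origin=vol.origin
    )


def write_mask(mask: NoduleMask, path: str | os.PathLike) -> None:
    # stored as uint8 0/1 for widest interoperability
    vol = CTVolume(
        voxels=mask.voxels.astype(np.uint8), spacing=mask.spacing, origin=mask.origin
    )
    write_volume(vol, path)


def _nodule_id_from_path(path) -> str:
    base = os.path.basename(os.fspath(path))
    for ext in SUPPORTED_EXTENSIONS:
        if base.lower().endswith(ext):
            return base[: -len(ext)]
    return base


# ---------------------------------------------------------------------------
# feature tables


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort feature table; returns it with canonical column order."""
    if len(table) == 0:
        raise ValidationError("cohort table is empty")
    missing_cols = [c for c in METADATA_COLUMNS + FEATURE_NAMES if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"cohort table missing columns: {missing_cols}")
    dup = table["nodule_id"][table["nodule_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate nodule identifiers: {sorted(dup.unique())}")
    feat = table[list(FEATURE_NAMES)]
    if feat.isna().any().any():
        bad = feat.isna()
        row, col = np.argwhere(bad.values)[0]
        raise ValidationError(
            f"missing feature value for nodule {table['nodule_id'].iloc[row]!r}, "
            f"column {feat.columns[col]!r}"
        )
    ordered = list(METADATA_COLUMNS) + list(FEATURE_NAMES)
    extras = [c for c in table.columns if c not in ordered]
    out = table[ordered + extras].copy()
    out["calcified"] = out["calcified"].astype(bool)
    out["subgroup"] = out["subgroup"].astype(bool)
    return out.reset_index(drop=True)


def write_feature_table(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a validated cohort table as CSV (floats at 12 significant digits)."""
    cohort = validate_cohort(cohort)
    cohort.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_cohort(table)
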