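"""Grid-aligned scalar volumes, label masks, and NIfTI I/O.

Conventions
-----------
Arrays are indexed ``(slice, row, col)``, 0-based.  ``spacing`` is millimetres
per axis in that same order.  The affine maps voxel indices (homogeneous) to
world coordinates in mm; volumes constructed in this package use a diagonal
affine built from the spacing, with the origin shifted when a volume is padded
so that voxel centres stay fixed in world space.

Every volume carries a physical-unit tag.  All thresholds in this package are
applied to these physical values (HU, Bq/mL, SUV), never to raw stored ints.

NIfTI round-trips go through :func:`write_volume` / :func:`read_volume`, which
pair each ``.nii.gz`` with a small JSON sidecar recording the unit (and, for a
patient volume, acquisition metadata) because NIfTI itself has no unit field
for activity concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigError, GridMismatchError

#: Recognised physical-unit tags.
UNITS = ("HU", "Bq/mL", "SUV", "dimensionless")

#: Label values used by bone masks.
BACKGROUND, MARROW, CORTEX = 0, 1, 2

#: Named regions resolvable against a label volume.
REGIONS = ("whole_bone", "marrow", "cortex")


def _affine_from_spacing(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel spacing and a physical-unit tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    unit: str
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigError(f"Volume3D data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("Volume3D data must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.unit not in UNITS:
            raise ConfigError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ConfigError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (spacing is mm; 1 mL = 1 cm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "Volume3D":
        """Copy of this volume with new data (same grid), optionally re-tagged."""
        return Volume3D(np.asarray(data, dtype=float), self.spacing,
                        unit or self.unit, self.affine.copy())


@dataclass
class RegionMask:
    """Integer label volume aligned to a :class:`Volume3D` grid.

    Binary masks use labels {0, 1}; bone masks use {0 background, 1 marrow,
    2 cortex}.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.dtype == bool:
            self.labels = self.labels.astype(np.int16)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigError("RegionMask labels must be integer (or bool)")
        if self.labels.ndim != 3:
            raise ConfigError("RegionMask labels must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def as_bool(self) -> np.ndarray:
        return self.labels > 0

    def count(self, region: str = "whole_bone") -> int:
        return int(np.count_nonzero(self.select(region)))

    def select(self, region: str) -> np.ndarray:
        """Boolean voxel selector for a named region."""
        if region == "whole_bone":
            return self.labels > 0
        if region == "marrow":
            return self.labels == MARROW
        if region == "cortex":
            return self.labels == CORTEX
        raise ConfigError(f"unknown region {region!r}; expected one of {REGIONS}")

    @classmethod
    def like(cls, vol: Volume3D, labels: np.ndarray) -> "RegionMask":
        return cls(labels, vol.spacing, vol.affine.copy())


def check_same_grid(a, b, what: str = "volumes") -> None:
    """Raise :class:`GridMismatchError` unless the two objects share a grid."""
    if a.shape != b.shape:
        raise GridMismatchError(f"{what} differ in shape: {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise GridMismatchError(
            f"{what} differ in affine:\n{a.affine}\nvs\n{b.affine}"
        )


# ----------------------------------------------------------------------------
# NIfTI I/O
# ----------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: Volume3D | RegionMask, path, extra_meta: dict | None = None) -> Path:
    """Write a volume or mask as NIfTI with a JSON sidecar for the unit tag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, RegionMask):
        data, unit = vol.labels.astype(np.int16), "dimensionless"
    else:
        data, unit = vol.data, vol.unit
    img = nib.Nifti1Image(np.asarray(data), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    sidecar = {"unit": unit, "spacing_mm": list(vol.spacing)}
    if extra_meta:
        sidecar.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path, unit: str | None = None) -> Volume3D:
    """Load a NIfTI volume; unit from the sidecar unless given explicitly."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ConfigError(f"not a readable NIfTI file: {path} ({exc})") from exc
    sidecar = _sidecar_path(path)
    if unit is None:
        if not sidecar.exists():
            raise ConfigError(
                f"no unit declared for {path}: sidecar {sidecar} missing and no "
                "unit argument given"
            )
        unit = json.loads(sidecar.read_text())["unit"]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(img.dataobj, dtype=float), spacing, unit,
                    np.asarray(img.affine))


def read_mask(path) -> RegionMask:
    """Load a NIfTI label volume as a :class:`RegionMask`."""
    vol = read_volume(path, unit="dimensionless")
    return RegionMask(np.rint(vol.data).astype(np.int16), vol.spacing, vol.affine)
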