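"""Volume and mask I/O on a common template grid.

All images in a cohort are assumed to be skull-stripped and affinely
co-registered to one template grid before they reach this package, so grid
identity is defined by shape and voxel spacing only; full affine orientation
bookkeeping is delegated to the registration step performed upstream. Voxel
indices are 0-based throughout, and mask/volume correspondence is by
identical index.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "BinaryMask",
    "GridMismatchError",
    "GridReport",
    "MASK_NAMES",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_same_grid",
    "ensure_same_grid",
    "read_manifest",
    "write_manifest",
]

#: Canonical anatomical mask identifiers: amygdala, entorhinal area,
#: hippocampus, parahippocampal gyrus, temporal lobe, lateral ventricles,
#: and the union of the six.
MASK_NAMES = ("AMG", "ENT", "HIP", "PHG", "TL", "LV", "OVALL")

SPACING_TOL_MM = 1e-6


class GridMismatchError(ValueError):
    """Raised when volumes/masks that must share a grid do not."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar image on a template grid.

    Parameters
    ----------
    data:
        3D array of intensities (any real dtype).
    spacing:
        Per-axis voxel size in millimetres.
    brain_mask:
        Optional boolean array of the same shape marking brain voxels.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    brain_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"volume axes must be positive, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape:
                raise ValueError(
                    "brain_mask shape "
                    f"{self.brain_mask.shape} does not match data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class BinaryMask:
    """A named binary ROI mask on the template grid (selected = 1)."""

    data: np.ndarray
    name: str
    spacing: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask '{self.name}' has values outside {{0,1}}: {vals[:5]}")
            arr = arr.astype(bool)
        self.data = arr
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_volume(path: Union[str, Path]) -> Volume:
    """Read a NIfTI-1 image as a :class:`Volume`.

    Spacing is taken from the header pixdim. Non-3D images are rejected.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing)


def write_volume(volume: Volume, path: Union[str, Path]) -> Path:
    """Write a :class:`Volume` as NIfTI-1 with a diagonal affine from spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume.data), _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: Union[str, Path], name: Optional[str] = None) -> BinaryMask:
    """Read a binary NIfTI mask; values must be strictly in {0, 1}."""
    vol = read_volume(path)
    if name is None:
        name = Path(path).name.split(".")[0]
    return BinaryMask(data=vol.data, name=name, spacing=vol.spacing)


def write_mask(mask: BinaryMask, path: Union[str, Path],
               spacing: Optional[Sequence[float]] = None) -> Path:
    sp = tuple(spacing) if spacing is not None else (mask.spacing or (1.0, 1.0, 1.0))
    return write_volume(Volume(mask.data.astype(np.uint8), sp), path)


@dataclasses.dataclass
class GridReport:
    """Result of a grid-compatibility check over a set of volumes/masks."""

    ok: bool
    messages: list[str]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def _grid_of(item) -> tuple[tuple[int, ...], Optional[tuple[float, ...]]]:
    if isinstance(item, Volume):
        return item.data.shape, item.spacing
    if isinstance(item, BinaryMask):
        return item.data.shape, item.spacing
    arr = np.asarray(item)
    return arr.shape, None


def check_same_grid(items: Iterable, tol_mm: float = SPACING_TOL_MM) -> GridReport:
    """Check that all volumes/masks share one grid (shape + spacing).

    Spacings are compared within ``tol_mm`` millimetres. Raw arrays may be
    included; they are checked on shape only. Returns a :class:`GridReport`
    whose messages name the offending inputs. Use :func:`ensure_same_grid`
    to raise instead.
    """
    items = list(items)
    if not items:
        raise ValueError("check_same_grid requires a non-empty list")
    ref_shape, ref_spacing = _grid_of(items[0])
    messages: list[str] = []
    for i, item in enumerate(items[1:], start=1):
        shape, spacing = _grid_of(item)
        if shape != ref_shape:
            messages.append(f"item {i}: shape {shape} != reference shape {ref_shape}")
        if spacing is not None and ref_spacing is not None:
            if any(abs(a - b) > tol_mm for a, b in zip(spacing, ref_spacing)):
                messages.append(
                    f"item {i}: spacing {spacing} != reference spacing {ref_spacing}"
                )
    return GridReport(ok=not messages, messages=messages)


def ensure_same_grid(items: Iterable, tol_mm: float = SPACING_TOL_MM) -> None:
    """Raise :class:`GridMismatchError` unless all items share one grid."""
    report = check_same_grid(items, tol_mm=tol_mm)
    if not report.ok:
        raise GridMismatchError("; ".join(report.messages))


MANIFEST_COLUMNS = ["subject_id", "path", "label", "group"]


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read a subject manifest TSV with columns subject_id/path/label/group.

    Labels are +1 (patient) / -1 (control); both classes must be present and
    subject ids unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    df["label"] = df["label"].astype(int)
    return _validate_manifest(df)


def _validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dups}")
    bad = set(df["label"].unique()) - {1, -1}
    if bad:
        raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")
    if df["label"].nunique() < 2:
        raise ValueError("manifest must contain both classes (+1 and -1)")
    return df


def write_manifest(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _validate_manifest(df)
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)
    return path
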