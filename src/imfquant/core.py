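"""Domain types and NIfTI I/O for muscle MRI intensity analysis.

The carriers here are deliberately thin: a 3-D intensity volume with voxel
spacing, a named binary muscle ROI on the same voxel grid, and the 1-D
within-ROI intensity sample that every thresholding model consumes.  Masks
and images are never resampled between grids — a T2-weighted volume and a
Dixon volume each carry their own segmentation.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MUSCLE_LABELS",
    "IntensityVolume",
    "MuscleROI",
    "IntensitySample",
    "DixonPair",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "extract_roi_sample",
    "sample_to_csv",
]

#: The six muscle/side labels: lumbar multifidus, erector spinae and psoas
#: major, left and right.
MUSCLE_LABELS = ("LML", "LMR", "ESL", "ESR", "PML", "PMR")


class GridMismatchError(ValueError):
    """A mask was applied to a volume living on a different voxel grid."""


def _grid_id_from(shape: tuple[int, ...], affine: np.ndarray) -> str:
    """Opaque identifier of an acquisition grid (shape + affine digest)."""
    h = hashlib.sha1()
    h.update(np.asarray(shape, dtype=np.int64).tobytes())
    h.update(np.round(np.asarray(affine, dtype=np.float64), 6).tobytes())
    return h.hexdigest()[:12]


@dataclass(frozen=True)
class IntensityVolume:
    """A 3-D scalar image with voxel spacing, in the scanner's raw units.

    Intensities are used raw: no rescaling, histogram equalisation or
    bias-field correction is ever applied.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    grid_id: str

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            idx = tuple(int(i) for i in np.argwhere(~np.isfinite(data))[0])
            raise ValueError(f"non-finite intensity at voxel index {idx}")
        if data.min() < 0:
            idx = tuple(int(i) for i in np.argwhere(data < 0)[0])
            raise ValueError(f"negative intensity at voxel index {idx}")
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {spacing}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class MuscleROI:
    """A named binary mask on a specific image grid.

    Any nonzero voxel counts as inside the ROI; values other than {0, 1}
    trigger a warning.  The ROI can only be applied to a volume with the
    same ``grid_id``.
    """

    label: str
    mask: np.ndarray
    grid_id: str

    def __post_init__(self) -> None:
        if self.label not in MUSCLE_LABELS:
            raise ValueError(
                f"unknown muscle label {self.label!r}; expected one of {MUSCLE_LABELS}"
            )
        mask = np.asarray(self.mask)
        if not np.isin(np.unique(mask), (0, 1)).all():
            warnings.warn(
                f"mask for {self.label} contains values outside {{0,1}}; "
                "treating every nonzero voxel as inside",
                stacklevel=2,
            )
        mask = (mask != 0)
        if not mask.any():
            raise ValueError(f"mask for {self.label} selects no voxels")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class IntensitySample:
    """Within-ROI voxel intensities of one muscle, in row-major voxel order."""

    values: np.ndarray
    muscle_label: str
    n_voxels: int = field(default=-1)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64).ravel()
        if values.size < 1:
            raise ValueError("intensity sample is empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("intensity sample contains non-finite values")
        object.__setattr__(self, "values", values)
        n = self.n_voxels if self.n_voxels >= 0 else values.size
        if n != values.size:
            raise ValueError(f"n_voxels={n} does not match {values.size} values")
        object.__setattr__(self, "n_voxels", int(n))


@dataclass(frozen=True)
class DixonPair:
    """Registered Dixon fat and water volumes on a shared grid."""

    fat: IntensityVolume
    water: IntensityVolume

    def __post_init__(self) -> None:
        if self.fat.grid_id != self.water.grid_id:
            raise GridMismatchError(
                f"fat grid {self.fat.grid_id!r} != water grid {self.water.grid_id!r}"
            )
        if self.fat.shape != self.water.shape:
            raise ValueError(
                f"fat shape {self.fat.shape} != water shape {self.water.shape}"
            )

    @property
    def grid_id(self) -> str:
        return self.fat.grid_id


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a 3-D NIfTI-1 volume.

    Spacing is taken from the header; intensities are cast to float64
    without any value rescaling (``get_fdata`` honours the NIfTI scale
    slope/intercept, which is the file's declared physical scale, not a
    normalisation).  Trailing singleton dimensions are squeezed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(data))[0])
        raise ValueError(f"{path}: non-finite intensity at voxel index {idx}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(
        data=data, spacing=spacing, grid_id=_grid_id_from(data.shape, img.affine)
    )


def write_volume(volume: IntensityVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (float64 payload, diagonal affine from spacing)."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_mask(
    path: str | Path,
    label: str,
    *,
    value: int | None = None,
    label_map: str | Path | None = None,
) -> MuscleROI:
    """Read a muscle ROI from a NIfTI mask file.

    A plain binary file maps directly to one ROI.  Multi-label files are
    accepted with either an explicit integer ``value`` or a YAML sidecar
    ``label_map`` mapping muscle label -> integer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    grid_id = _grid_id_from(data.shape, img.affine)

    if label_map is not None:
        with open(label_map) as fh:
            mapping = yaml.safe_load(fh)
        if label not in mapping:
            raise KeyError(f"label {label!r} not present in label map {label_map}")
        value = int(mapping[label])
    if value is not None:
        mask = data == value
        if not mask.any():
            raise ValueError(f"{path}: no voxels carry label value {value}")
        return MuscleROI(label=label, mask=mask, grid_id=grid_id)
    return MuscleROI(label=label, mask=data, grid_id=grid_id)


def extract_roi_sample(volume: IntensityVolume, roi: MuscleROI) -> IntensitySample:
    """Collect the intensities of exactly the masked voxels, row-major.

    The order is deterministic (C-order scan of the grid), so repeated calls
    yield identical sequences and downstream per-voxel classifications align.
    """
    if volume.grid_id != roi.grid_id:
        raise GridMismatchError(
            f"ROI {roi.label} lives on grid {roi.grid_id!r}, "
            f"volume on grid {volume.grid_id!r}"
        )
    if volume.shape != roi.mask.shape:
        raise GridMismatchError(
            f"ROI {roi.label} shape {roi.mask.shape} != volume shape {volume.shape}"
        )
    values = volume.data[roi.mask]  # boolean indexing scans in C (row-major) order
    return IntensitySample(values=values, muscle_label=roi.label)


def sample_to_csv(sample: IntensitySample, path: str | Path) -> Path:
    """Export a sample as tidy CSV with columns muscle_label, intensity."""
    path = Path(path)
    pd.DataFrame(
        {"muscle_label": sample.muscle_label, "intensity": sample.values}
    ).to_csv(path, index=False)
    return path
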