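"""Grid-aligned 2-D image and mask containers plus NIfTI / CSV plumbing.

All processing in this package is two-dimensional: a single (central) lesion
slice on a common voxel grid shared by the SUV map, the DWI stack, the ADC map
and every mask.  Voxel indices are 0-based; the physical position of the
*center* of voxel ``(i, j)`` is ``origin + (i * spacing_row, j * spacing_col)``
in millimetres.  Crop boxes are half-open ``[min, max)`` index intervals.

Array axis 0 maps to NIfTI axis 0 and axis 1 to NIfTI axis 1; masks are stored
as unsigned 8-bit 0/1 images for interoperability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarSlice",
    "DWIStack",
    "BinaryMask",
    "CropBox",
    "crop",
    "read_slice",
    "write_slice",
    "read_mask",
    "write_mask",
    "read_bvalues",
    "write_bvalues",
    "read_cropbox",
    "write_cropbox",
]


def _check_spacing(spacing: tuple[float, float]) -> tuple[float, float]:
    spacing = (float(spacing[0]), float(spacing[1]))
    if not (spacing[0] > 0 and spacing[1] > 0):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    return spacing


@dataclass(frozen=True)
class ScalarSlice:
    """A 2-D scalar field (SUV, activity concentration or ADC) with geometry.

    Parameters
    ----------
    values
        2-D float array.  Units depend on the quantity: SUV is dimensionless
        (g/mL convention), ADC is in mm^2/s.
    spacing
        (row, col) voxel size in mm.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(
            self, "origin", (float(self.origin[0]), float(self.origin[1]))
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def position(self, i: int, j: int) -> tuple[float, float]:
        """Physical (mm) position of the center of voxel (i, j)."""
        return (
            self.origin[0] + i * self.spacing[0],
            self.origin[1] + j * self.spacing[1],
        )


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean lesion mask on the same grid contract as ScalarSlice."""

    mask: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            uniq = np.unique(mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be boolean or 0/1")
            mask = mask.astype(bool)
        if mask.ndim != 2 or mask.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(
            self, "origin", (float(self.origin[0]), float(self.origin[1]))
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def position(self, i: int, j: int) -> tuple[float, float]:
        return (
            self.origin[0] + i * self.spacing[0],
            self.origin[1] + j * self.spacing[1],
        )


@dataclass(frozen=True)
class DWIStack:
    """Aligned diffusion-weighted signal slices indexed by b-value.

    ``bvalues`` are in s/mm^2 and must be strictly increasing; every signal
    slice shares one shape and must be non-negative (magnitude images).
    """

    signals: tuple[np.ndarray, ...]
    bvalues: tuple[float, ...]
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        signals = tuple(np.asarray(s, dtype=float) for s in self.signals)
        bvalues = tuple(float(b) for b in self.bvalues)
        if len(signals) != len(bvalues):
            raise ValueError("one signal slice per b-value required")
        if len(signals) == 0:
            raise ValueError("empty DWI stack")
        if any(b < 0 for b in bvalues):
            raise ValueError("b-values must be non-negative")
        if any(b1 >= b2 for b1, b2 in zip(bvalues, bvalues[1:])):
            raise ValueError("b-values must be strictly increasing")
        shape = signals[0].shape
        for s in signals:
            if s.ndim != 2 or s.shape != shape or s.size == 0:
                raise ValueError("all signal slices must share one 2-D shape")
            if np.any(s < 0):
                raise ValueError("DWI magnitude signals must be >= 0")
        object.__setattr__(self, "signals", signals)
        object.__setattr__(self, "bvalues", bvalues)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))
        object.__setattr__(
            self, "origin", (float(self.origin[0]), float(self.origin[1]))
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.signals[0].shape  # type: ignore[return-value]

    def as_array(self) -> np.ndarray:
        """Stack signals into a (n_b, rows, cols) array."""
        return np.stack(self.signals, axis=0)


@dataclass(frozen=True)
class CropBox:
    """Half-open rectangular voxel-index box ``[row_min, row_max) x [col_min, col_max)``."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        for name in ("row_min", "row_max", "col_min", "col_max"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("crop box indices must be non-negative")
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise ValueError("crop box must have positive extent")

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.row_max > shape[0] or self.col_max > shape[1]:
            raise ValueError(f"crop box {self} exceeds array extent {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_min, self.row_max), slice(self.col_min, self.col_max))


def crop(slc: ScalarSlice, box: CropBox) -> ScalarSlice:
    """Extract the sub-slice under ``box``, shifting the origin accordingly.

    The physical position of any voxel in the crop equals its position in the
    uncropped slice.
    """
    box.check_within(slc.shape)
    return ScalarSlice(
        values=slc.values[box.slices()].copy(),
        spacing=slc.spacing,
        origin=(
            slc.origin[0] + box.row_min * slc.spacing[0],
            slc.origin[1] + box.col_min * slc.spacing[1],
        ),
    )


# ---------------------------------------------------------------------------
# NIfTI plumbing


def _affine(spacing: tuple[float, float], origin: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = spacing[0]
    aff[1, 1] = spacing[1]
    aff[0, 3] = origin[0]
    aff[1, 3] = origin[1]
    return aff


def _load_2d(path: str | Path, slice_index: int | None) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises its own hierarchy
        raise ValueError(f"{path} is not a readable NIfTI image: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim == 3:
        if slice_index is None:
            raise ValueError("3-D image requires an explicit slice_index")
        if not (0 <= slice_index < data.shape[2]):
            raise ValueError(
                f"slice_index {slice_index} out of range for {data.shape[2]} slices"
            )
        data = data[:, :, slice_index]
    elif data.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:2]
    origin = (float(img.affine[0, 3]), float(img.affine[1, 3]))
    return np.asarray(data, dtype=float), (float(zooms[0]), float(zooms[1])), origin


def read_slice(path: str | Path, slice_index: int | None = None) -> ScalarSlice:
    """Read a scalar map from NIfTI; 3-D images require ``slice_index`` (0-based)."""
    data, spacing, origin = _load_2d(path, slice_index)
    return ScalarSlice(values=data, spacing=spacing, origin=origin)


def write_slice(slc: ScalarSlice, path: str | Path) -> None:
    img = nib.Nifti1Image(
        slc.values.astype(np.float64), _affine(slc.spacing, slc.origin)
    )
    nib.save(img, str(path))


def read_mask(path: str | Path, slice_index: int | None = None) -> BinaryMask:
    data, spacing, origin = _load_2d(path, slice_index)
    return BinaryMask(mask=data > 0.5, spacing=spacing, origin=origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.mask.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# CSV plumbing (b-values, crop boxes)


def read_bvalues(path: str | Path) -> list[float]:
    """Read a one-column CSV of b-values in s/mm^2 (optional 'bvalue' header)."""
    out: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            tok = row[0].strip()
            try:
                out.append(float(tok))
            except ValueError:
                if not out and tok.lower() in ("b", "bvalue", "b_value"):
                    continue
                raise ValueError(f"unparseable b-value entry {tok!r}")
    if not out:
        raise ValueError(f"no b-values found in {path}")
    return out


def write_bvalues(bvalues: list[float], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bvalue"])
        for b in bvalues:
            w.writerow([f"{b:g}"])


def read_cropbox(path: str | Path) -> CropBox:
    """Read a crop box CSV with header row_min,row_max,col_min,col_max."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(fh)]
    if not rows:
        raise ValueError(f"no crop box row in {path}")
    r = rows[0]
    return CropBox(
        row_min=int(r["row_min"]),
        row_max=int(r["row_max"]),
        col_min=int(r["col_min"]),
        col_max=int(r["col_max"]),
    )


def write_cropbox(box: CropBox, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["row_min", "row_max", "col_min", "col_max"])
        w.writerow([box.row_min, box.row_max, box.col_min, box.col_max])
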