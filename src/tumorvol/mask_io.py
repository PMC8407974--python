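"""Reading and writing binary segmentation masks and cohort tables.

Masks are stored as NIfTI-1 volumes. Internally every mask uses the layout
``(slice, row, col)`` — axis 0 is the axial (slice) axis — with physical
spacing ``(dz, dy, dx)`` in millimetres. Files whose anatomical orientation
places the superior–inferior axis elsewhere are transposed on load.

A voxel with index ``(k, i, j)`` occupies the closed box centred at the
physical point ``(k*dz, i*dy, j*dx)`` with extents ``(dz, dy, dx)``. All
physical measurements downstream use this voxel model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import MaskError

log = logging.getLogger(__name__)

__all__ = ["SegmentationMask", "load_mask", "save_mask", "write_table", "read_table"]


@dataclass(frozen=True)
class SegmentationMask:
    """A 3D binary voxel grid with physical spacing.

    Parameters
    ----------
    voxels:
        3D array of {0, 1}, indexed ``(slice, row, col)``.
    spacing:
        ``(dz, dy, dx)`` in mm, all strictly positive.
    case_id:
        Identifier carried through to tables and reports.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise MaskError(f"mask must be 3D, got {vox.ndim}D")
        vals = np.unique(vox)
        if not np.isin(vals, (0, 1)).all():
            raise MaskError(f"mask voxels must be 0/1, found values {vals[:5]}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(not np.isfinite(s) or s <= 0 for s in sp):
            raise MaskError(f"spacing must be three positive finite numbers, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


def _axial_axis(img: nib.Nifti1Image) -> int:
    """Index of the data axis running superior–inferior (the axial slice axis)."""
    hdr = img.header
    if int(hdr["sform_code"]) == 0 and int(hdr["qform_code"]) == 0:
        log.warning("no orientation metadata; assuming the slowest-varying axis is axial")
        return img.ndim - 1
    axcodes = nib.aff2axcodes(img.affine)
    for ax, code in enumerate(axcodes):
        if code in ("S", "I"):
            return ax
    log.warning("orientation %s lacks an S/I axis; assuming the slowest-varying axis is axial", axcodes)
    return img.ndim - 1


def load_mask(path: str | Path, case_id: str = "") -> SegmentationMask:
    """Load a binary mask from NIfTI, reorienting to ``(slice, row, col)``.

    A two-valued source ``{0, v}`` is mapped to {0, 1}; more than two distinct
    values is a multi-label error. Spacing comes from the header zooms.
    """
    path = Path(path)
    if not path.exists():
        raise MaskError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MaskError(f"expected a 3D volume, got {data.ndim}D in {path}")
    vals = np.unique(data)
    if vals.size > 2:
        raise MaskError(f"multi-label mask ({vals.size} distinct values) in {path}")
    binary = (data > 0).astype(np.uint8)
    # NIfTI pixdim is float32; round to nm precision so written spacings
    # round-trip to their original double values
    zooms = [float(round(float(z), 6)) for z in img.header.get_zooms()[:3]]
    ax = _axial_axis(img)
    binary = np.moveaxis(binary, ax, 0)
    inplane = [zooms[a] for a in range(3) if a != ax]
    spacing = (zooms[ax], inplane[0], inplane[1])
    if not case_id:
        case_id = path.name.removesuffix(".gz").removesuffix(".nii")
    return SegmentationMask(voxels=binary, spacing=spacing, case_id=case_id)


def save_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a mask as integer NIfTI that round-trips through :func:`load_mask`.

    The file stores axes ``(row, col, slice)`` with an RAS-positive affine, so
    the axial axis is the slowest-varying one — the conventional NIfTI layout.
    """
    dz, dy, dx = mask.spacing
    arr = np.transpose(mask.voxels, (1, 2, 0)).astype(np.uint8)
    affine = np.diag([dy, dx, dz, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort tables


def write_table(records: Sequence, path: str | Path, float_format: str = "%.12g") -> None:
    """Write records (objects exposing ``as_row() -> dict``) to CSV.

    All records must share one column schema; the column order of the first
    record is the documented file order. Floats are written with >= 10
    significant digits so that :func:`read_table` inverts this function.
    """
    rows = [r.as_row() if hasattr(r, "as_row") else dict(r) for r in records]
    if rows:
        cols = list(rows[0].keys())
        for k, r in enumerate(rows[1:], start=2):
            if list(r.keys()) != cols:
                raise MaskError(f"record {k} schema differs from record 1")
        frame = pd.DataFrame(rows, columns=cols)
    else:
        from .records import COHORT_COLUMNS

        frame = pd.DataFrame(columns=COHORT_COLUMNS)
    frame.to_csv(path, index=False, float_format=float_format)


def read_table(path: str | Path) -> list:
    """Read a cohort CSV written by :func:`write_table` back into records."""
    from .records import CohortRecord

    frame = pd.read_csv(path)
    return [CohortRecord.from_row(row) for _, row in frame.iterrows()]


def read_frame(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV as a plain DataFrame (one row per case)."""
    return pd.read_csv(path)
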