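"""Volumetric and tabular I/O for the ReHo pipeline.

Owns the pipeline's grid, affine and coordinate conventions:

* voxel indices are 0-based ``(i, j, k)`` triples;
* world coordinates are whatever the affine encodes (MNI millimetres for
  spatially normalized data);
* masks must share the functional grid exactly — no resampling happens here.

Motion traces follow the SPM ``rp_*.txt`` dialect: six whitespace-delimited
columns per volume, three translations in mm followed by three rotations
stored in radians; rotations are converted to degrees on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ["id", "group", "age", "gender", "education", "hama"]


class VolumeError(ValueError):
    """Raised for malformed or inconsistent volumetric inputs."""


@dataclass
class Volume4D:
    """A subject's 4D BOLD time series.

    Attributes
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel intensities in arbitrary units.
    affine : ndarray, shape (4, 4)
        Voxel-index (0-based) to world-mm map.
    tr : float
        Repetition time in seconds per volume.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise VolumeError("not a 4D time series")
        if any(s < 3 for s in self.data.shape[:3]):
            raise VolumeError("spatial dimensions must each be >= 3")
        if self.data.shape[3] < 2:
            raise VolumeError("need at least 2 time points")
        _check_affine(self.affine)
        if not (self.tr > 0):
            raise VolumeError(f"tr must be positive, got {self.tr}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """3D binary mask sharing a grid with the volumes it gates."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeError("mask must be 3D")
        _check_affine(self.affine)
        if not self.data.any():
            raise VolumeError("mask has no in-mask voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_matches(self, vol: Volume4D) -> None:
        """Masks must match the functional grid exactly; no resampling."""
        if self.data.shape != vol.data.shape[:3]:
            raise VolumeError(
                f"mask shape {self.data.shape} does not match volume grid "
                f"{vol.data.shape[:3]}"
            )
        if not np.allclose(self.affine, vol.affine, atol=1e-4):
            raise VolumeError("mask affine does not match volume affine")


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion estimates.

    ``translations`` are (t, 3) in mm; ``rotations`` are (t, 3) in degrees
    (converted from the radians stored on disk).
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("motion trace needs matching (t, 3) translation/rotation arrays")
        if len(self.translations) < 1:
            raise ValueError("empty motion trace")

    @property
    def n_volumes(self) -> int:
        return len(self.translations)


@dataclass
class DesignTable:
    """Per-subject group labels and nuisance covariates."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("no subjects in design table")
        ids = self.table["id"].astype(str)
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate subject ids: {dups}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].astype(str).unique())

    def subjects_in(self, group: str) -> list[str]:
        sel = self.table["group"].astype(str) == group
        return self.table.loc[sel, "id"].astype(str).tolist()

    def row(self, subject_id: str) -> pd.Series:
        sel = self.table["id"].astype(str) == str(subject_id)
        if not sel.any():
            raise KeyError(f"subject {subject_id!r} not in design table")
        return self.table.loc[sel].iloc[0]


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise VolumeError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeError("affine is not invertible")


def read_volume4d(path: str | Path, tr: float | None = None) -> Volume4D:
    """Read a 4D NIfTI-1 time series.

    The repetition time is taken from the time-axis pixdim; if the header
    records no positive TR, ``tr`` must be supplied explicitly (silent
    defaults would corrupt the band-pass filter downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise VolumeError(f"not a 4D time series: {path} has {img.ndim} dimensions")
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    # convert ms/us encodings to seconds when the header declares them
    t_unit = img.header.get_xyzt_units()[1]
    if t_unit == "msec":
        header_tr /= 1e3
    elif t_unit == "usec":
        header_tr /= 1e6
    if header_tr > 0:
        tr_val = header_tr
    elif tr is not None and tr > 0:
        tr_val = float(tr)
    else:
        raise VolumeError(
            f"{path}: header records no repetition time and none was supplied"
        )
    return Volume4D(data=data, affine=img.affine, tr=tr_val)


def write_volume4d(vol: Volume4D, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], vol.tr))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def write_map3d(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D statistical or concordance map as NIfTI-1."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise VolumeError(f"map must be 3D, got {data.ndim} dimensions")
    nib.save(nib.Nifti1Image(data.astype(np.float32), np.asarray(affine, float)), str(path))


def read_mask(path: str | Path) -> BrainMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise VolumeError(f"mask must be 3D: {path} has {img.ndim} dimensions")
    return BrainMask(data=np.asarray(img.dataobj), affine=img.affine)


def write_mask(mask: BrainMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def voxel_to_world(
    index: tuple[int, int, int],
    affine: np.ndarray,
    shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Map a 0-based voxel index to world-mm coordinates via the affine."""
    idx = np.asarray(index)
    if idx.shape != (3,):
        raise ValueError("index must be a triple")
    if np.any(idx < 0):
        raise IndexError(f"negative voxel index {tuple(idx)}")
    if shape is not None and np.any(idx >= np.asarray(shape)):
        raise IndexError(f"voxel index {tuple(idx)} outside grid {shape}")
    homo = np.asarray(affine, dtype=float) @ np.array([idx[0], idx[1], idx[2], 1.0])
    return homo[:3]


def world_to_voxel(world: tuple[float, float, float], affine: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns the nearest voxel index."""
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    homo = inv @ np.array([world[0], world[1], world[2], 1.0])
    return np.rint(homo[:3]).astype(int)


def read_motion(path: str | Path) -> MotionTrace:
    """Read an SPM-style rp_*.txt file (3 translations mm, 3 rotations rad)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such motion file: {path}")
    try:
        arr = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable motion file ({exc})") from exc
    if arr.size == 0:
        raise ValueError(f"{path}: empty motion file")
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, found {arr.shape[1]}")
    logger.info("%s: rotations converted from radians to degrees", path)
    return MotionTrace(translations=arr[:, :3], rotations=np.degrees(arr[:, 3:]))


def write_motion(trace: MotionTrace, path: str | Path) -> None:
    """Write a motion trace in the rp_*.txt dialect (rotations in radians)."""
    arr = np.hstack([trace.translations, np.radians(trace.rotations)])
    np.savetxt(str(path), arr, fmt="%.8e")


def read_design(path: str | Path) -> DesignTable:
    """Read the subject/covariate design CSV (header ``id,group,age,gender,education,hama``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such design file: {path}")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: no subjects")
    bad_rows = []
    for col in ("age", "education", "hama"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows.extend((df.index[coerced.isna() & df[col].notna()] + 2).tolist())
            df[col] = coerced
    if bad_rows:
        raise ValueError(f"{path}: unparseable numeric values at lines {sorted(set(bad_rows))}")
    return DesignTable(table=df)


def write_design(design: DesignTable, path: str | Path) -> None:
    design.table.to_csv(path, index=False, columns=DESIGN_COLUMNS)


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the spatial affine)."""
    A = np.asarray(affine, dtype=float)[:3, :3]
    return np.linalg.norm(A, axis=0)


def affine_has_shear(affine: np.ndarray, tol: float = 1e-6) -> bool:
    """True if the spatial axes are not mutually orthogonal."""
    A = np.asarray(affine, dtype=float)[:3, :3]
    gram = A.T @ A
    off = gram - np.diag(np.diag(gram))
    return bool(np.max(np.abs(off)) > tol * np.max(np.abs(np.diag(gram))))
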