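"""Readers and writers for CT slice stacks, mask stacks and the cohort table.

Slice stacks are directories of per-slice TIFF/PNG images, ordered by
lexicographic filename, or single NIfTI volumes. Binary masks are written
either as single-channel PNGs storing ``{0, 255}`` or as NIfTI volumes
storing ``{0, 1}``; on read any PNG value >= 128 counts as foreground.
"""
from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .grids import DEFAULT_SPACING_MM, COMPARTMENTS, LabelMask, VoxelGrid

_SLICE_EXTENSIONS = (".tif", ".tiff", ".png")
_NIFTI_EXTENSIONS = (".nii", ".nii.gz")

COHORT_COLUMNS = ("patient_id", "compartment", "bvtv", "tb_th", "tb_sp", "tb_n", "volume")
_COHORT_NUMERIC = ("bvtv", "tb_th", "tb_sp", "tb_n", "volume", "mgv")

#: Packaged fixture transcribed from a 24-patient post-ACLR cohort
#: (48 tunnels: femur and tibia per patient).
COHORT_FIXTURE = Path(__file__).parent / "data" / "table4_cohort.csv"


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def _list_slice_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in _SLICE_EXTENSIONS
    )
    return files


def read_slice_stack(
    path: str | os.PathLike,
    spacing: float = DEFAULT_SPACING_MM,
    patient_id: str | None = None,
    compartment: str | None = None,
) -> VoxelGrid:
    """Read a CT stack from a slice directory or a NIfTI volume file.

    Directory slices are ordered by lexicographic filename; reading the same
    directory twice yields identical grids. 8/16-bit intensities are
    preserved bit-exactly.
    """
    if not spacing > 0:
        raise ValueError(f"bad spacing: {spacing!r} (must be > 0)")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    if path.is_dir():
        files = _list_slice_files(path)
        if not files:
            raise ValueError(f"no slices: directory {path} contains no image files")
        slices = [_read_image(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"ragged stack: slice shapes differ: {sorted(shapes)}")
        if slices[0].ndim != 2:
            raise ValueError("slices must be single-channel 2D images")
        volume = np.stack(slices, axis=0)
    elif _is_nifti(path):
        img = nib.load(str(path))
        volume = np.asanyarray(img.dataobj)
        if volume.ndim != 3:
            raise ValueError(f"NIfTI volume must be 3D, got ndim={volume.ndim}")
    else:
        # single-image stack of one slice
        volume = _read_image(path)
        if volume.ndim != 2:
            raise ValueError("single slice file must be a 2D image")
        volume = volume[None]

    return VoxelGrid(volume, spacing=spacing, patient_id=patient_id, compartment=compartment)


def write_slice_stack(grid: VoxelGrid, path: str | os.PathLike, fmt: str = "tiff") -> list[Path]:
    """Write a grid as per-slice images (``slice_0000.tif`` ...)."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": ".tif", "png": ".png"}.get(fmt)
    if ext is None:
        raise ValueError(f"unknown format: {fmt!r}")
    written = []
    for i, sl in enumerate(grid.intensities):
        out = directory / f"slice_{i:04d}{ext}"
        if ext == ".tif":
            tifffile.imwrite(out, sl)
        else:
            iio.imwrite(out, sl)
        written.append(out)
    return written


def write_mask_stack(
    mask: LabelMask, path: str | os.PathLike, dialect: str = "png255"
) -> list[Path]:
    """Write a 3D binary mask as per-slice PNGs ({0,255}) or a NIfTI volume ({0,1}).

    Read-back through :func:`read_mask_stack` reproduces the mask exactly.
    """
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    path = Path(path)
    if dialect == "png255":
        path.mkdir(parents=True, exist_ok=True)
        written = []
        for i, sl in enumerate(mask.values):
            out = path / f"mask_{i:04d}.png"
            iio.imwrite(out, (sl * 255).astype(np.uint8))
            written.append(out)
        return written
    if dialect == "nifti":
        if path.is_dir() or not _is_nifti(path):
            path = (path / "mask.nii.gz") if path.is_dir() else Path(str(path) + ".nii.gz")
        path.parent.mkdir(parents=True, exist_ok=True)
        img = nib.Nifti1Image(mask.values.astype(np.uint8), affine=np.eye(4))
        nib.save(img, str(path))
        return [path]
    raise ValueError(f"unknown dialect: {dialect!r}")


def read_mask_stack(path: str | os.PathLike) -> LabelMask:
    """Read a mask written by :func:`write_mask_stack` (either dialect).

    PNG pixels >= 128 are read as foreground.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise ValueError(f"no slices: directory {path} contains no mask PNGs")
        slices = [np.asarray(iio.imread(f)) >= 128 for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError("ragged stack: mask slice shapes differ")
        return LabelMask(np.stack(slices).astype(np.uint8))
    img = nib.load(str(path))
    return LabelMask((np.asanyarray(img.dataobj) > 0).astype(np.uint8))


def load_cohort_table(path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Load a per-tunnel morphometry table (one row per patient/compartment).

    Without a path, loads the packaged 24-patient fixture (48 rows). The CSV
    must provide ``patient_id, compartment, bvtv, tb_th, tb_sp, tb_n, volume``
    and may carry an optional ``mgv`` column.
    """
    path = COHORT_FIXTURE if path is None else Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table schema error: missing columns {missing}")
    for col in _COHORT_NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"cohort table parse error: non-numeric {col!r} at row {idx}")
        df[col] = coerced
    bad_comp = ~df["compartment"].isin(COMPARTMENTS)
    if bad_comp.any():
        raise ValueError(f"unknown compartment values: {sorted(df.loc[bad_comp, 'compartment'].unique())}")
    if df.duplicated(subset=["patient_id", "compartment"]).any():
        raise ValueError("duplicate (patient_id, compartment) keys")
    if ((df["bvtv"] < 0) | (df["bvtv"] > 1)).any():
        raise ValueError("bvtv out of [0, 1]")
    for col in ("tb_th", "tb_sp", "tb_n", "volume"):
        if (df[col] < 0).any():
            raise ValueError(f"{col} must be non-negative")
    return df.reset_index(drop=True)
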