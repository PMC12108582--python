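"""Core volumetric containers: intensity grids and binary label masks.

Arrays are indexed ``(slice, row, col)``, 0-based. Voxel spacing is a single
isotropic scalar in millimetres carried as metadata; the default of 0.0607 mm
is the XtremeCT-II HR-pQCT voxel size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: XtremeCT-II isotropic voxel edge length, mm (60.7 um).
DEFAULT_SPACING_MM = 0.0607

COMPARTMENTS = ("femur", "tibia")


@dataclass
class VoxelGrid:
    """A 3D scalar CT intensity volume with isotropic voxel spacing.

    Parameters
    ----------
    intensities
        Array of shape ``(n_slices, n_rows, n_cols)`` with finite,
        non-negative values. Stored intensities are preserved as read; no
        Hounsfield or BMD calibration is applied.
    spacing
        Isotropic voxel edge length in mm (> 0).
    patient_id
        Opaque patient label, optional.
    compartment
        ``"femur"`` or ``"tibia"``, optional.
    """

    intensities: np.ndarray
    spacing: float = DEFAULT_SPACING_MM
    patient_id: str | None = None
    compartment: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (slice, row, col), got ndim={self.intensities.ndim}"
            )
        if min(self.intensities.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if not self.spacing > 0:
            raise ValueError(f"bad spacing: {self.spacing!r} (must be > 0)")
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(self.spacing) ** 3


@dataclass
class LabelMask:
    """A binary 2D or 3D mask over ``{0, 1}`` aligned to a grid or slice."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim not in (2, 3):
            raise ValueError(f"mask must be 2D or 3D, got ndim={arr.ndim}")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.values = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def count(self) -> int:
        """Number of foreground voxels/pixels."""
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def check_paired(self, other) -> None:
        """Raise if this mask's shape differs from a paired grid/mask."""
        other_shape = getattr(other, "shape", other)
        if tuple(self.shape) != tuple(other_shape):
            raise ValueError(
                f"shape mismatch: mask {self.shape} vs paired {tuple(other_shape)}"
            )
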