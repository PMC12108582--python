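"""3D tunnel reconstruction and trabecular morphometry.

Per-slice tunnel masks are stacked into a 3D region of interest (no
inter-slice smoothing) and the standard model-independent indices are
computed inside it:

* **BV/TV** — mineralized fraction: bone voxels / tunnel voxels (exact
  voxel-count ratio).
* **Tb.Th** (mm) — volume-weighted mean local thickness of the bone phase.
* **Tb.Sp** (mm) — mean local thickness of the non-bone phase inside the
  tunnel.
* **Tb.N** (1/mm) — direct method: reciprocal of the mean spacing between
  bone-phase mid-axes, measured as the local thickness of the region with
  the bone skeleton removed; a plate-model alternative (BV/TV / Tb.Th) is
  available via config.
* **volume** (mm^3) — tunnel voxel count times the voxel volume, exact.
* **mGV** — mean grayscale value of the original intensities inside the
  tunnel (unweighted mean of per-slice means).

Local thickness at a voxel is the diameter of the largest sphere that lies
entirely inside the structure and covers the voxel, computed from the
Euclidean distance transform by painting spheres in decreasing-radius
order. Sphere radii use the surface convention (EDT minus half a voxel), so
an n-voxel slab measures n voxels thick.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grids import LabelMask, VoxelGrid
from .metrics import mean_grayscale


@dataclass(frozen=True)
class MorphometryConfig:
    """Knobs for :func:`morphometry_report`.

    ``bone_threshold``: ``None`` selects Otsu's method on tunnel-interior
    intensities; a number fixes the bone/background cut directly.
    ``tbn_method``: ``"direct"`` (mid-axis spacing) or ``"plate"``
    (BV/TV / Tb.Th model formula).
    """

    bone_threshold: float | None = None
    tbn_method: str = "direct"
    compute_mgv: bool = True

    def __post_init__(self):
        if self.tbn_method not in ("direct", "plate"):
            raise ValueError("tbn_method must be 'direct' or 'plate'")


@dataclass(frozen=True)
class MorphometryResult:
    """One tunnel's morphometry (one row of a cohort table)."""

    bvtv: float          # unitless fraction in [0, 1]
    tb_th: float         # mm
    tb_sp: float         # mm
    tb_n: float          # 1/mm
    volume: float        # mm^3
    mgv: float | None = None  # intensity units

    def as_dict(self) -> dict:
        return {
            "bvtv": self.bvtv,
            "tb_th_mm": self.tb_th,
            "tb_sp_mm": self.tb_sp,
            "tb_n_per_mm": self.tb_n,
            "volume_mm3": self.volume,
            "mgv": self.mgv,
        }


def _mask_values(mask) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.values
    return LabelMask(np.asarray(mask)).values


def tunnel_volume(mask, spacing: float) -> float:
    """Tunnel volume in mm^3: voxel count times spacing cubed, exactly."""
    if not spacing > 0:
        raise ValueError("bad spacing")
    return int(_mask_values(mask).sum()) * spacing**3


def _bone_threshold(grid: VoxelGrid, roi: np.ndarray, method: str | float):
    """Bone/background cut and its comparison mode, from ROI intensities.

    Returns ``(threshold, strict)``: bone is ``intensity > threshold`` when
    strict (Otsu's upper background edge) else ``intensity >= threshold``.
    """
    inside = grid.intensities[roi]
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown method: {method!r}")
        if np.ptp(inside) == 0:
            # uniform interior: no separable phases; everything >= the single
            # value counts as bone, matching the fixed-threshold convention
            return float(inside.flat[0]), False
        return float(threshold_otsu(inside)), True
    return float(method), False


def bone_in_tunnel(grid: VoxelGrid, tunnel, method: str | float = "otsu") -> LabelMask:
    """Binary bone mask inside the tunnel ROI.

    ``method``: ``"otsu"`` computes the threshold from tunnel-interior
    intensities only; a number is used as a fixed threshold (bone =
    intensity >= value). The result is always a subset of the tunnel mask.
    """
    t = _mask_values(tunnel)
    if t.shape != grid.shape:
        raise ValueError(f"shape mismatch: tunnel {t.shape} vs grid {grid.shape}")
    sel = t.astype(bool)
    if not sel.any():
        raise ValueError("empty tunnel mask")
    thr, strict = _bone_threshold(grid, sel, method)
    inside = grid.intensities[sel]
    bone = np.zeros(grid.shape, dtype=np.uint8)
    bone[sel] = ((inside > thr) if strict else (inside >= thr)).astype(np.uint8)
    return LabelMask(bone)


def local_thickness_map(mask, spacing: float = 1.0) -> np.ndarray:
    """Hildebrand–Rüegsegger local thickness of a 3D structure, in mm.

    thickness(x) = diameter of the largest sphere contained in the
    structure that covers x. Computed by thresholding the Euclidean
    distance transform at each candidate radius (descending) and dilating
    by that radius, so every voxel records the largest covering sphere.
    Zero outside the structure; an empty mask yields an all-zero map.
    """
    structure = _mask_values(mask).astype(bool)
    if structure.ndim != 3:
        raise ValueError("mask must be 3D")
    out = np.zeros(structure.shape, dtype=np.float64)
    if not structure.any():
        return out
    edt = ndimage.distance_transform_edt(structure)
    # surface convention: sphere radius measured to the structure boundary
    radius = np.maximum(edt - 0.5, 0.0)
    for r in np.unique(radius[structure])[::-1]:
        centers = radius >= r - 1e-9
        if r <= 0.5:
            covered = centers
        else:
            # voxels within r of any center: EDT from the center set
            covered = ndimage.distance_transform_edt(~centers) <= r + 1e-9
        covered &= structure
        newly = covered & (out == 0)
        out[newly] = 2.0 * r
    return out * spacing


def _mean_thickness(structure: np.ndarray, roi: np.ndarray, spacing: float) -> float:
    """Volume-weighted mean local thickness of ``structure``, averaged over
    the structure voxels lying inside ``roi``.

    The thickness map is computed on the full structure so spheres are not
    artificially truncated at the ROI boundary.
    """
    sel = structure & roi
    if not sel.any():
        return 0.0
    tmap = local_thickness_map(structure.astype(np.uint8), spacing)
    return float(tmap[sel].mean())


def distance_ridge(structure: np.ndarray) -> np.ndarray:
    """Mid-axis of a structure: local maxima of its distance transform.

    For a plate lattice this is the mid-plane sheet of each plate. Unlike a
    topological (curve) skeleton, the ridge keeps sheet-like mid-axes, which
    is what inter-trabecular spacing must be measured against.
    """
    structure = structure.astype(bool)
    if not structure.any():
        return structure
    edt = ndimage.distance_transform_edt(structure)
    ridge = structure & (edt >= ndimage.maximum_filter(edt, size=3) - 1e-9)
    return ridge


def trabecular_number(bone: np.ndarray, roi: np.ndarray, spacing: float) -> float:
    """Direct Tb.N: 1 / mean spacing between bone-phase mid-axes, per mm.

    The bone mid-axes (distance-transform ridge) partition space; the mean
    spacing between adjacent mid-axes is the mean local thickness of the
    complement of the ridge, averaged inside the ROI, plus one voxel for the
    ridge sheet itself. For a plate lattice of period p this gives spacing p
    and Tb.N = 1/p. Returns 0 when the ROI holds no bone.
    """
    bone = bone.astype(bool)
    roi = roi.astype(bool)
    if not (bone & roi).any():
        return 0.0
    ridge = distance_ridge(bone)
    if not ridge.any():
        return 0.0
    between = ~ridge
    mean_gap = _mean_thickness(between, roi, spacing)
    # the ridge sheet itself occupies one voxel of each gap
    mean_gap += spacing
    if mean_gap <= 0:
        return 0.0
    return 1.0 / mean_gap


def morphometry_report(
    grid: VoxelGrid,
    tunnel,
    config: MorphometryConfig | None = None,
) -> MorphometryResult:
    """Full trabecular morphometry of one reconstructed tunnel."""
    config = config or MorphometryConfig()
    t = _mask_values(tunnel)
    if t.shape != grid.shape:
        raise ValueError("shape mismatch between tunnel mask and grid")
    roi = t.astype(bool)
    if not roi.any():
        raise ValueError("empty tunnel mask")

    method = "otsu" if config.bone_threshold is None else config.bone_threshold
    thr, strict = _bone_threshold(grid, roi, method)
    # phases are binarized over the whole grid (threshold learned inside the
    # ROI) so thickness spheres are not truncated at the ROI boundary;
    # indices are then averaged over ROI voxels only
    bone_global = (grid.intensities > thr) if strict else (grid.intensities >= thr)

    n_roi = int(roi.sum())
    n_bone = int((bone_global & roi).sum())
    bvtv = n_bone / n_roi

    spacing = grid.spacing
    tb_th = _mean_thickness(bone_global, roi, spacing)
    tb_sp = _mean_thickness(~bone_global, roi, spacing)

    if config.tbn_method == "plate":
        tb_n = bvtv / tb_th if tb_th > 0 else 0.0
    else:
        tb_n = trabecular_number(bone_global, roi, spacing)

    mgv = None
    if config.compute_mgv:
        _, mgv = mean_grayscale(grid, LabelMask(t))

    return MorphometryResult(
        bvtv=bvtv,
        tb_th=tb_th,
        tb_sp=tb_sp,
        tb_n=tb_n,
        volume=tunnel_volume(LabelMask(t), spacing),
        mgv=mgv,
    )


def crop_roi(grid: VoxelGrid, mask, size: int = 338) -> tuple[VoxelGrid, LabelMask]:
    """Center-crop grid and mask to ``size`` x ``size`` in-plane.

    Mirrors the analysis-frame convention of cropping the network frame to
    a smaller square before texture analysis; a crop, never a resample.
    """
    values = _mask_values(mask)
    if values.shape != grid.shape:
        raise ValueError("shape mismatch")
    _, h, w = grid.shape
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds slice size {h}x{w}")
    r0, c0 = (h - size) // 2, (w - size) // 2
    sub = grid.intensities[:, r0:r0 + size, c0:c0 + size]
    sub_mask = values[:, r0:r0 + size, c0:c0 + size]
    return (
        VoxelGrid(sub, spacing=grid.spacing, patient_id=grid.patient_id,
                  compartment=grid.compartment),
        LabelMask(sub_mask),
    )
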