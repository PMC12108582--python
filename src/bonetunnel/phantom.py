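"""Synthetic trabecular phantoms with carved graft tunnels.

Real post-ACLR HR-pQCT scans show a bright trabecular lattice interrupted by
a roughly cylindrical low-density drill tunnel that partially refills with
new bone over time. This module generates such volumes with known geometry —
a parallel-plate lattice (bright plates of thickness ``t`` repeating with
period ``p``) carved by a slice-aligned cylinder — together with per-slice
ground-truth tunnel masks and a closed-form morphometry oracle:

    BV/TV = t/p,   Tb.Th = t,   Tb.Sp = p - t,   Tb.N = 1/p.

Plates are the default lattice because every index has a closed form; a rod
lattice has no such oracle here and is rejected.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grids import DEFAULT_SPACING_MM, LabelMask, VoxelGrid


@dataclass(frozen=True)
class TunnelAxis:
    """A slice-aligned (perpendicular-to-slice) cylinder axis.

    ``center_row``/``center_col`` are voxel coordinates of the axis in every
    slice; ``slice_start``/``slice_stop`` bound the cylinder along the stack
    (half-open, ``None`` meaning the full extent).
    """

    center_row: float
    center_col: float
    slice_start: int | None = None
    slice_stop: int | None = None


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of a lattice-plus-tunnel phantom.

    Geometry is in mm; intensities are on the 8-bit-like scale of the HR-pQCT
    exports (bone bright, background dark). ``refill_fraction`` is the
    fraction of carved tunnel voxels restored to bone intensity, emulating
    early bone fill inside the tunnel.
    """

    shape: tuple[int, int, int] = (40, 64, 64)
    spacing: float = 0.05
    lattice_kind: str = "plates"
    plate_thickness_t: float = 0.3
    plate_period_p: float = 1.0
    bone_intensity: float = 180.0
    background_intensity: float = 40.0
    noise_sd: float = 0.0
    tunnel_axis: TunnelAxis | None = None
    tunnel_radius: float = 0.0
    refill_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_kind not in ("plates", "rods"):
            raise ValueError(f"unknown lattice_kind: {self.lattice_kind!r}")
        if not 0 < self.plate_thickness_t < self.plate_period_p:
            raise ValueError(
                "spec error: require 0 < plate_thickness_t < plate_period_p, got "
                f"t={self.plate_thickness_t}, p={self.plate_period_p}"
            )
        if not self.bone_intensity > self.background_intensity:
            raise ValueError("bone_intensity must exceed background_intensity")
        if self.tunnel_radius < 0:
            raise ValueError("tunnel_radius must be >= 0")
        if not 0.0 <= self.refill_fraction <= 1.0:
            raise ValueError("refill_fraction must be in [0, 1]")
        if self.spacing <= 0:
            raise ValueError("bad spacing")


@dataclass
class PhantomSample:
    """A generated phantom: intensity grid plus bone and tunnel ground truth."""

    grid: VoxelGrid
    bone_truth: LabelMask
    tunnel_truth: LabelMask
    spec: PhantomSpec


def _plate_bone_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean bone lattice: plates normal to the row axis."""
    n_rows = spec.shape[1]
    # voxel centre position along the plate-normal axis, mm
    pos = (np.arange(n_rows) + 0.5) * spec.spacing
    in_plate = (pos % spec.plate_period_p) < spec.plate_thickness_t
    bone = np.zeros(spec.shape, dtype=bool)
    bone[:, in_plate, :] = True
    return bone


def make_lattice_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate a parallel-plate trabecular lattice (no tunnel yet).

    Bone voxels take ``bone_intensity`` and background voxels
    ``background_intensity``; zero-mean Gaussian noise of sd ``noise_sd`` is
    added on top. Deterministic for a fixed ``spec.seed``.
    """
    if spec.lattice_kind != "plates":
        raise NotImplementedError("only the plate lattice is implemented")
    bone = _plate_bone_mask(spec)
    intensities = np.where(bone, spec.bone_intensity, spec.background_intensity).astype(np.float64)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensities = intensities + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        np.clip(intensities, 0.0, None, out=intensities)
    grid = VoxelGrid(intensities, spacing=spec.spacing)
    sample = PhantomSample(
        grid=grid,
        bone_truth=LabelMask(bone.astype(np.uint8)),
        tunnel_truth=LabelMask(np.zeros(spec.shape, dtype=np.uint8)),
        spec=spec,
    )
    if spec.tunnel_axis is not None and spec.tunnel_radius > 0:
        sample = carve_tunnel(sample, spec.tunnel_axis, spec.tunnel_radius, spec.refill_fraction)
    return sample


def cylinder_mask(shape: tuple[int, int, int], spacing: float,
                  axis: TunnelAxis, radius_mm: float) -> np.ndarray:
    """Boolean slice-aligned cylinder: the tunnel footprint (or an analysis ROI)."""
    return _cylinder_mask(shape, spacing, axis, radius_mm)


def _cylinder_mask(shape: tuple[int, int, int], spacing: float,
                   axis: TunnelAxis, radius_mm: float) -> np.ndarray:
    n_slices, n_rows, n_cols = shape
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    r_vox = radius_mm / spacing
    disk = (rr - axis.center_row) ** 2 + (cc - axis.center_col) ** 2 <= r_vox**2
    mask = np.zeros(shape, dtype=bool)
    lo = 0 if axis.slice_start is None else max(0, axis.slice_start)
    hi = n_slices if axis.slice_stop is None else min(n_slices, axis.slice_stop)
    mask[lo:hi] = disk
    return mask


def carve_tunnel(
    sample: PhantomSample,
    axis: TunnelAxis,
    radius: float,
    refill_fraction: float = 0.0,
) -> PhantomSample:
    """Carve a slice-aligned cylindrical tunnel into a phantom.

    Voxels within ``radius`` (mm) of the axis drop to background intensity
    and are recorded in ``tunnel_truth``; a seeded random fraction
    ``refill_fraction`` of the carved voxels is restored to bone intensity
    (and ``bone_truth``) to emulate partial bone regrowth. With
    ``refill_fraction == 0`` the bone and tunnel truths are disjoint.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    shape = sample.grid.shape
    if not (0 <= axis.center_row < shape[1] and 0 <= axis.center_col < shape[2]):
        raise ValueError(f"axis ({axis.center_row}, {axis.center_col}) outside grid {shape[1:]}")
    if radius == 0:
        return sample

    spec = sample.spec
    tunnel = _cylinder_mask(shape, sample.grid.spacing, axis, radius)
    intensities = sample.grid.intensities.copy()
    bone = sample.bone_truth.as_bool().copy()
    intensities[tunnel] = spec.background_intensity
    bone[tunnel] = False

    if refill_fraction > 0:
        rng = np.random.default_rng(spec.seed + 1)
        idx = np.flatnonzero(tunnel.ravel())
        n_refill = int(round(refill_fraction * idx.size))
        chosen = rng.choice(idx, size=n_refill, replace=False)
        flat = intensities.ravel()
        flat[chosen] = spec.bone_intensity
        bone.ravel()[chosen] = True

    if spec.noise_sd > 0:
        rng_noise = np.random.default_rng(spec.seed + 2)
        noise = rng_noise.normal(0.0, spec.noise_sd, size=shape)
        intensities[tunnel] = np.clip(intensities[tunnel] + noise[tunnel], 0.0, None)

    new_spec = replace(spec, tunnel_axis=axis, tunnel_radius=radius,
                       refill_fraction=refill_fraction)
    return PhantomSample(
        grid=VoxelGrid(intensities, spacing=sample.grid.spacing,
                       patient_id=sample.grid.patient_id,
                       compartment=sample.grid.compartment),
        bone_truth=LabelMask(bone.astype(np.uint8)),
        tunnel_truth=LabelMask(tunnel.astype(np.uint8)),
        spec=new_spec,
    )


def expected_lattice_metrics(spec: PhantomSpec) -> dict:
    """Closed-form morphometry of a plate lattice.

    For plates of thickness ``t`` repeating with period ``p``:
    ``BV/TV = t/p``, ``Tb.Th = t`` mm, ``Tb.Sp = p - t`` mm, ``Tb.N = 1/p``
    per mm. ``volume`` is the voxelized tunnel volume in mm^3 when a tunnel
    is specified, else the whole-grid volume.
    """
    if spec.lattice_kind != "plates":
        raise ValueError("oracle not defined for lattice_kind != 'plates'")
    t, p = spec.plate_thickness_t, spec.plate_period_p
    if spec.tunnel_axis is not None and spec.tunnel_radius > 0:
        tunnel = _cylinder_mask(spec.shape, spec.spacing, spec.tunnel_axis, spec.tunnel_radius)
        volume = float(tunnel.sum()) * spec.spacing**3
    else:
        volume = float(np.prod(spec.shape)) * spec.spacing**3
    return {
        "bvtv": t / p,
        "tb_th": t,
        "tb_sp": p - t,
        "tb_n": 1.0 / p,
        "volume": volume,
    }


def make_training_set(
    spec: PhantomSpec, n: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n`` (slice image, tunnel mask) training pairs.

    Each pair comes from a fresh phantom whose tunnel axis position and
    radius are jittered around the template ``spec``; the mask is the
    per-slice tunnel ground truth. Deterministic for a fixed ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    _, n_rows, n_cols = spec.shape
    base_radius = spec.tunnel_radius if spec.tunnel_radius > 0 else 0.25 * n_rows * spec.spacing
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n):
        axis = TunnelAxis(
            center_row=float(rng.uniform(0.3, 0.7) * n_rows),
            center_col=float(rng.uniform(0.3, 0.7) * n_cols),
        )
        radius = float(base_radius * rng.uniform(0.7, 1.3))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = replace(spec, tunnel_axis=axis, tunnel_radius=radius, seed=sub_seed)
        sample = make_lattice_phantom(sub)
        k = sample.grid.n_slices // 2
        pairs.append((sample.grid.intensities[k].copy(),
                      sample.tunnel_truth.values[k].copy()))
    return pairs
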