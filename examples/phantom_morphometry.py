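"""Morphometry of a synthetic trabecular plate phantom.

Builds a parallel-plate lattice (plates 0.3 mm thick, 1.0 mm period) whose
indices have closed forms — BV/TV = t/p, Tb.Th = t, Tb.Sp = p - t,
Tb.N = 1/p — analyzes a cylindrical region of interest, and compares the
recovered values against the oracle. Agreement is within one voxel on the
thickness metrics and 0.02 on BV/TV.
"""
import numpy as np

from bonetunnel import (
    LabelMask, PhantomSpec, TunnelAxis,
    expected_lattice_metrics, make_lattice_phantom, morphometry_report,
)
from bonetunnel.phantom import cylinder_mask

spec = PhantomSpec(shape=(50, 60, 60), spacing=0.1,
                   plate_thickness_t=0.3, plate_period_p=1.0, noise_sd=0.0)
sample = make_lattice_phantom(spec)
roi = LabelMask(cylinder_mask(spec.shape, spec.spacing,
                              TunnelAxis(30, 30), 2.0).astype(np.uint8))

res = morphometry_report(sample.grid, roi)
exp = expected_lattice_metrics(spec)

print(f"{'index':<10}{'measured':>10}{'closed form':>14}")
for key, meas, true in [("BV/TV", res.bvtv, exp["bvtv"]),
                        ("Tb.Th", res.tb_th, exp["tb_th"]),
                        ("Tb.Sp", res.tb_sp, exp["tb_sp"]),
                        ("Tb.N", res.tb_n, exp["tb_n"])]:
    print(f"{key:<10}{meas:>10.3f}{true:>14.3f}")
print(f"\nROI volume: {res.volume:.2f} mm^3 "
      f"({roi.count()} voxels x {spec.spacing} mm cubed)")
print("Thickness metrics are in mm, Tb.N in 1/mm; small residuals come "
      "from voxelizing the plates.")
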