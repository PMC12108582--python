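"""Inter-observer agreement tables and mean grayscale values.

Simulates three annotators who outline the same tunnel cross-sections with
slightly different margins (dilated/eroded variants of the true cylinder),
scores every annotator pair with precision, recall, mean IoU and mean
pixel accuracy, and extracts the mean grayscale value (mGV) of the tunnel
interior — the intensity proxy for how much bone has regrown inside.
"""
import numpy as np
from scipy import ndimage

from bonetunnel import (
    LabelMask, PhantomSpec, TunnelAxis, carve_tunnel,
    make_lattice_phantom, mean_grayscale, pairwise_agreement,
)

spec = PhantomSpec(shape=(6, 64, 64), spacing=0.05, noise_sd=6.0, seed=11)
sample = carve_tunnel(make_lattice_phantom(spec), TunnelAxis(32, 32), 0.9,
                      refill_fraction=0.3)
truth = sample.tunnel_truth.values

annotators = {
    "D1": {i: truth[i] for i in range(truth.shape[0])},
    "D2": {i: ndimage.binary_dilation(truth[i]).astype(np.uint8)
           for i in range(truth.shape[0])},
    "D3": {i: ndimage.binary_erosion(truth[i]).astype(np.uint8)
           for i in range(truth.shape[0])},
}
table = pairwise_agreement(annotators)
print("pairwise agreement (fractions; first source plays the prediction role):")
print(table.round(4).to_string(), "\n")

per_slice, sequence = mean_grayscale(sample.grid, sample.tunnel_truth)
print(f"per-slice mGV: {[f'{v:.1f}' for v in per_slice]}")
print(f"sequence mGV:  {sequence:.2f}")
print("With 30% of the tunnel refilled with bright bone, the mGV sits "
      "between the background and bone intensity levels.")
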