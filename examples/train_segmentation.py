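"""Train the reduced-width tunnel-segmentation network on phantom slices.

Draws 8 synthetic CT slices with ground-truth tunnel masks, trains the
desk-scale residual U-net variant for 200 steps under the dice loss, and
evaluates the prediction on a training slice. The network memorizes the
tiny set (dice > 0.95), demonstrating that the architecture, loss and
optimizer wiring can fit tunnel cross-sections.

Runs in well under a minute on a laptop CPU.
"""
import numpy as np

from bonetunnel import PhantomSpec, VoxelGrid, make_training_set, segmentation_scores
from bonetunnel.nn import ModelSpec, TrainConfig, build_model, predict_stack, train

spec = PhantomSpec(shape=(3, 64, 64), spacing=0.05, noise_sd=5.0,
                   tunnel_radius=0.8, seed=7)
pairs = make_training_set(spec, 8, seed=7)
print(f"{len(pairs)} slice/mask pairs, {pairs[0][0].shape} pixels each")

model = build_model(ModelSpec.small(seed=0))
config = TrainConfig(epochs=200, batch_size=8, learning_rate=2e-2,
                     lr_decay_every=200, seed=0)
history = train(model, pairs, config)
print(f"dice loss: {history[0]:.3f} (first epoch) -> {history[-1]:.3f} (last)")
print(f"training dice: {1 - history[-1]:.3f}")

grid = VoxelGrid(np.stack([img for img, _ in pairs]), spacing=spec.spacing)
pred = predict_stack(model, grid)
scores = segmentation_scores(pred.values[0], pairs[0][1])
print(f"training-slice IoU {scores.iou:.3f}, precision {scores.precision:.3f}, "
      f"recall {scores.recall:.3f}")
print("IoU near 1 means the predicted tunnel cross-section overlays the "
      "ground-truth cylinder almost voxel-for-voxel.")
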