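"""Compare two segmentations with overlap and surface-distance metrics.

Takes a phantom's ground truth, simulates an imperfect prediction by
shifting it one voxel, and prints hard Dice, average boundary distance and
Hausdorff distance per structure.  A one-voxel shift of a small structure
costs a lot of Dice but only ~1 mm of boundary distance — the reason both
kinds of metric are reported.
"""

import numpy as np

from hypothseg.io import LabelMap
from hypothseg.metrics import evaluate_segmentation
from hypothseg.phantom import PhantomConfig, generate_phantom

_, gt = generate_phantom(PhantomConfig.desk(32, seed=2))

shifted = np.zeros_like(gt.data)
shifted[:, 1:, :] = gt.data[:, :-1, :]  # one voxel along anterior-posterior
pred = LabelMap(shifted, gt.taxonomy, gt.voxel_size, gt.affine)

report = evaluate_segmentation(pred, gt)
table = report.to_frame().round(3)
print(table.to_string(index=False))
print("\nDice drops well below 1 for the small subunits although every")
print("boundary voxel is only 1 mm from its true position (avg distance ~<1).")
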