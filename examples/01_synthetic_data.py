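"""Generate a synthetic fundus image with its microaneurysm mask.

The generator emulates the statistics the segmentation method targets:
a circular field of view, textured orange background, dark vessel
strokes, and a handful of tiny dark lesions that are the only positive
pixels in the mask.
"""

import numpy as np

from masegnet import SynthConfig, generate_fundus

config = SynthConfig(image_size=512, seed=7)
image, mask = generate_fundus(config)

n_lesion_px = int(mask.sum())
print(f"image shape: {image.shape}, dtype {image.dtype}")
print(f"lesion pixels: {n_lesion_px} "
      f"({100 * n_lesion_px / mask.size:.3f}% of the frame)")
print(f"green-channel mean inside FOV: "
      f"{image[..., 1][image[..., 1] > 0].mean():.1f}")

# The lesion fraction far below 1% is the class imbalance that motivates
# patch-based training and Dice/IoU (rather than accuracy) evaluation.
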