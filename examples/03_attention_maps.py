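"""Inspect the three attention mechanisms on a feature map.

Channel attention squeezes each channel to one weight in (0,1); spatial
attention produces a per-pixel weight map; the attention gate scales a
skip connection by coefficients computed against the coarser decoder
signal.  All three are multiplicative contractions: they can only
down-weight activations, never amplify them.
"""

import numpy as np

from masegnet.nn import Tensor
from masegnet.model import CBAM, AttentionGate

rng = np.random.default_rng(0)
features = rng.standard_normal((1, 8, 16, 16)).astype(np.float32)

cbam = CBAM(channels=8, reduction=4, rng=np.random.default_rng(1))
mc = cbam.channel(Tensor(features)).data
ms = cbam.spatial(Tensor(mc * features)).data
refined = cbam(Tensor(features)).data

print(f"channel weights M_c ({mc.shape}): {np.round(mc.ravel(), 3)}")
print(f"spatial map M_s range: ({ms.min():.3f}, {ms.max():.3f})")
print(f"contraction holds: {bool(np.all(np.abs(refined) <= np.abs(features)))}")

gate = AttentionGate(skip_channels=8, gating_channels=16, inter_channels=4,
                     rng=np.random.default_rng(2))
skip = rng.standard_normal((1, 8, 16, 16)).astype(np.float32)
gating = rng.standard_normal((1, 16, 8, 8)).astype(np.float32)
alpha = gate.alpha(Tensor(skip), Tensor(gating)).data
print(f"attention-gate alpha range: ({alpha.min():.3f}, {alpha.max():.3f})")

# Every weight lies strictly inside (0,1): the sigmoid gates select, the
# network learns what to suppress during training.
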