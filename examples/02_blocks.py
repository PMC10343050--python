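"""The three computational blocks, run standalone on toy tensors.

Shows that periodic down-shuffling is a lossless (invertible)
rearrangement, that an HDC block is far lighter than the dense 3x3x3
convolution it replaces, and that the global attention mechanism only
ever attenuates its input.
"""

import numpy as np

from hdcseg import GAM, GAMConfig, HDCBlock, HDCConfig, pds_downshuffle, pds_inverse
from hdcseg.autograd import Tensor
from hdcseg.nn import count_parameters

rng = np.random.default_rng(0)

# --- PDS: (C, D, H, W) -> (8C, D/2, H/2, W/2), exactly invertible
x = rng.normal(size=(4, 32, 32, 32)).astype(np.float32)
y = pds_downshuffle(x)
back = pds_inverse(y)
print(f"PDS: {x.shape} -> {y.shape}; round-trip exact: {np.array_equal(back, x)}")

# --- HDC: parameter count vs a dense 3^3 convolution at equal widths
blk = HDCBlock(HDCConfig(in_channels=64, out_channels=64), rng=rng)
dense = 64 * 64 * 27
print(f"HDC 64->64: {count_parameters(blk)} parameters "
      f"(dense 3x3x3 would need {dense})")

# --- GAM: sigmoid gates in (0,1) mean the output never exceeds the input
gam = GAM(GAMConfig(channels=16, reduction=4, spatial_kernel=3), rng=rng)
f1 = rng.normal(size=(1, 16, 8, 8, 8)).astype(np.float32)
f3 = gam(Tensor(f1)).data
print(f"GAM: max |output|/|input| ratio = {np.max(np.abs(f3) / (np.abs(f1) + 1e-9)):.3f} (< 1)")
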