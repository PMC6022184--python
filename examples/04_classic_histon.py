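"""The classic fixed-neighbourhood histon on a toy image.

The original histon uses a P x Q sliding window and a scalar expanse E: a
pixel counts twice in its intensity bin when the summed squared difference to
its neighbours stays below E.  This reference mode illustrates the limiting
behaviours that also bound the supervoxel variant.
"""

import numpy as np

from svhiston import classic_histon

rng = np.random.default_rng(0)
# two flat regions with a noisy border: spatial structure the histogram misses
image = np.zeros((32, 32), dtype=np.int64)
image[:, 16:] = 200
image += rng.integers(0, 8, image.shape)

for E in (0.0, 2000.0, np.inf):
    histons, histograms = classic_histon(image, (3, 3), expanse=E)
    ratio = histons[0].sum() / histograms[0].sum()
    print(f"E={E:>8}: histon mass / histogram mass = {ratio:.3f}")

# E=0 collapses the histon onto the histogram (no pixel is "similar", strict
# inequality); E=inf doubles it (every pixel is similar).  In between, the
# mass ratio measures how much of the image is locally homogeneous at
# tolerance E — border pixels fail the test, interior pixels pass.
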