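"""Analytic anchor values of the DSSIM image distance.

DSSIM = 1 - SSIM lies in [0, 2]: 0 between identical images, ~1 between an
all-black and an all-white image (only the luminance term survives), and
approaching 2 for anti-correlated images of equal brightness.
"""

import numpy as np

from modmap import dssim

side = 512
black = np.zeros((side, side))
white = np.full((side, side), 255.0)
rng = np.random.default_rng(0)
random_image = rng.integers(0, 256, (side, side)).astype(float)
i, j = np.indices((side, side))
checker = 255.0 * ((i + j) % 2)

print(f"identical images   : {dssim(random_image, random_image):.6f}  (exactly 0)")
print(f"black vs white     : {dssim(black, white):.6f}  (~1, luminance only)")
print(f"checker vs inverse : {dssim(checker, 255.0 - checker):.6f}  (-> 2, anti-correlated)")
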