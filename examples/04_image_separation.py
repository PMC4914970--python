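"""Blind separation of mixed synthetic images.

Four source images (three oriented textures plus one white-noise channel,
all with bounded sub-Gaussian pixel histograms) are superposed by a random
4x4 mixing matrix.  Training on one mixed pixel at a time with a uniform
source prior recovers the original images up to permutation, sign and
scale.
"""

import numpy as np

from eghr import generate_synthetic_images, run_image_bss

stack = generate_synthetic_images(4, (64, 64), seed=0)

rng = np.random.default_rng(7)
A = rng.standard_normal((4, 4))
while np.linalg.cond(A) > 6:
    A = rng.standard_normal((4, 4))

recon, report = run_image_bss(stack, A, n_steps=10_000_000, tau_W=5e3, seed=1)
print("source -> matched output:", report.permutation)
print("|correlation| per source:", np.round(report.correlations, 4))
print("worst-recovered source:   %.4f" % report.min_correlation)
# Correlations near 1 mean each reconstructed image is (up to sign and
# scale) the original source; the white-noise channel is recovered too.
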