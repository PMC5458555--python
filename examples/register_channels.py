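"""Recover the donor->acceptor channel mapping from fiducial beads.

Multi-colour beads appear in both halves of the split camera image; their
matched centroids determine the affine transform used to pair each donor
spot with its acceptor counterpart.
"""

import numpy as np

from mxfret import simulate_bead_field, fit_affine, apply_affine

# a realistic split-view mapping: slight magnification difference, small
# rotation, and a large lateral offset between the two camera halves
true_matrix = np.array([[1.002, -0.004], [0.004, 0.998]])
true_offset = np.array([256.0, 2.5])

donor_pts, acceptor_pts = simulate_bead_field(
    n_beads=40, true_map=(true_matrix, true_offset), noise_sd=0.2, seed=7
)

amap = fit_affine(donor_pts, acceptor_pts)
print(f"fitted on {amap.n_points} beads, residual rms = {amap.residual_rms:.3f} px")
print(f"linear part:\n{np.round(amap.matrix, 4)}")
print(f"offset: {np.round(amap.offset, 2)} px (truth: {true_offset})")

# mapping quality over the whole field of view
grid = np.random.default_rng(0).uniform(0, 512, (500, 2))
ideal = grid @ true_matrix.T + true_offset
err = np.linalg.norm(apply_affine(amap, grid) - ideal, axis=1)
print(f"mean mapping error across the field: {err.mean():.3f} px")
# With 0.2 px centroid noise and 40 beads the recovered map is accurate to a
# few hundredths of a pixel, far below the spot-pairing tolerance.
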