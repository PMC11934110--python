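"""Path-signature basics: closed forms, Levy area, reparameterization.

The signature of a path is its sequence of iterated integrals: level 1 is
the net displacement, level 2 encodes signed areas, and the whole object is
invariant to how fast the path is traversed.
"""

import numpy as np

from neurotraj import compute_signature
from neurotraj.signatures import signature_features

# one straight segment: S^1 = v - u, S^2 = (v-u) outer (v-u) / 2
u, v = np.array([0.0, 0.0]), np.array([3.0, 4.0])
sig = compute_signature(np.vstack([u, v]), depth=2)
print("level 1 (displacement):", sig.levels[0])
print("level 2 diag (outer/2):", np.diag(sig.levels[1]))

# counterclockwise unit square: the antisymmetric part of level 2 is the
# enclosed (Levy) area = 1
square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
s2 = compute_signature(square, depth=2).levels[1]
print("Levy area of unit square:", (s2[0, 1] - s2[1, 0]) / 2)

# reparameterization invariance: resampling the same piecewise-linear image
# at irregular times leaves the signature unchanged
rng = np.random.default_rng(0)
path = rng.normal(size=(8, 2))
t = np.linspace(0, 1, 8)
t_new = np.sort(np.concatenate([t, rng.uniform(0, 1, 20)]))
warped = np.column_stack([np.interp(t_new, t, path[:, j]) for j in range(2)])
a = compute_signature(path, 3).levels[2]
b = compute_signature(warped, 3).levels[2]
print("max level-3 difference after time warp:", float(np.abs(a - b).max()))

# the full featurization (standardize -> rescale -> signature -> per-level
# normalization) gives a d + d^2 feature vector per latent trajectory
feats = signature_features(rng.normal(size=(50, 8)), depth=2)
print("feature vector length for d=8, N=2:", feats.shape[0], "(8 + 64)")
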