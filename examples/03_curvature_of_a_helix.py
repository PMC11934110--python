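"""Validate the curvature estimator on curves with known curvature.

A circle of radius r has curvature 1/r everywhere; a helix
(cos t, sin t, c t) has constant curvature R/(R^2 + c^2).  The estimator
fits a circle in the local SVD plane around each point (neighborhood = 8%
of the curve) and reports kappa = 1/r.
"""

import numpy as np

from neurotraj import curvature_profile

# circle of radius 2, arbitrarily rotated in 3-D
rng = np.random.default_rng(0)
Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
t = np.linspace(0, 2 * np.pi, 300, endpoint=False)
circle = np.column_stack([2 * np.cos(t), 2 * np.sin(t), np.zeros_like(t)]) @ Q.T
prof = curvature_profile(circle, neighborhood_fraction=0.08)
print(f"circle r=2: mean kappa = {np.nanmean(prof.kappa):.4f} (exact 0.5)")

# helix with R=1, c=0.5: kappa = 1 / (1 + 0.25) = 0.8
t = np.linspace(0, 6 * np.pi, 500)
helix = np.column_stack([np.cos(t), np.sin(t), 0.5 * t])
prof = curvature_profile(helix, neighborhood_fraction=0.08)
print(f"helix R=1, c=0.5: mean kappa = {np.nanmean(prof.kappa):.4f} (exact 0.8)")

# straight line: kappa = 0 (degenerate neighborhoods are detected exactly)
line = np.outer(np.linspace(0, 1, 200), [1.0, 1.0, 1.0])
prof = curvature_profile(line, neighborhood_fraction=0.08)
print(f"line: max kappa = {np.nanmax(prof.kappa):.4f} (exact 0)")
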