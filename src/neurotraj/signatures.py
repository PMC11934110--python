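"""Truncated path signatures of latent trajectories.

The level-k signature of a d-dimensional path h'(t) is the d^k tensor of
iterated integrals

    S^k_{i1..ik} = \\int_{0<t1<...<tk<1} dh'_{i1}(t1) ... dh'_{ik}(tk).

For a piecewise-linear path the signature is exact: each linear segment with
increment D contributes the tensor exponential (D^{(x)k} / k!) and segments
chain by Chen's identity, S(x * y) = S(x) (x) S(y).  Signatures are invariant
to time reparameterization of the path's image, which is why they summarize
trajectory *shape* irrespective of traversal speed.

The featurization pipeline mirrors the analysis design: standardize each
path component to zero mean and unit variance (population sd; constant
components are zeroed and flagged), affinely rescale the time interval to
[0, 1], compute the truncated signature, then normalize each level to unit
Euclidean norm so no level dominates the downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoencoder import LatentTrajectory

__all__ = [
    "SignatureFeature",
    "PathStandardization",
    "standardize_path",
    "rescale_time",
    "compute_signature",
    "normalize_signature",
    "signature_features",
]

_MAX_FEATURES = 10**7


@dataclass
class PathStandardization:
    """Per-component standardization statistics and the original time span."""

    mu: np.ndarray
    sigma: np.ndarray
    constant: np.ndarray  # flag: components with zero variance (set to 0)
    a: float
    b: float


@dataclass
class SignatureFeature:
    """Truncated signature: levels S^1..S^N; level k is a tensor with d^k entries."""

    levels: list[np.ndarray]
    d: int
    normalized: bool = False

    @property
    def depth(self) -> int:
        return len(self.levels)

    def flatten(self) -> np.ndarray:
        """Concatenate levels 1..N in lexicographic index order."""
        return np.concatenate([lvl.reshape(-1) for lvl in self.levels])


def standardize_path(
    h: np.ndarray, a: float = 0.0, b: float = 1.0
) -> tuple[np.ndarray, PathStandardization]:
    """Standardize each component of a tau x d path to mean 0, sd 1.

    Population standard deviation (divide by tau).  Constant components are
    mapped to zero and flagged in the returned statistics.
    """
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] < 2:
        raise ValueError("path must be tau x d with tau >= 2")
    mu = h.mean(axis=0)
    sigma = h.std(axis=0)  # population sd
    constant = sigma == 0.0
    centered = h - mu
    out = np.divide(centered, sigma, out=np.zeros_like(centered), where=~constant)
    return out, PathStandardization(mu=mu, sigma=sigma, constant=constant, a=a, b=b)


def rescale_time(times: np.ndarray, a: float, b: float) -> np.ndarray:
    """Affine map of [a, b] onto the standard interval [0, 1]."""
    if b <= a:
        raise ValueError("need b > a")
    times = np.asarray(times, dtype=np.float64)
    return (times - a) / (b - a)


def _segment_levels(delta: np.ndarray, depth: int) -> list[np.ndarray]:
    """Signature levels of one linear segment: delta^{(x)k} / k!."""
    levels = [delta.copy()]
    for k in range(2, depth + 1):
        levels.append(np.multiply.outer(levels[-1], delta) / k)
    return levels


def chen_product(
    left: list[np.ndarray], right: list[np.ndarray], d: int
) -> list[np.ndarray]:
    """Chen's identity: levels of the concatenated path from two halves.

    Level k of the product is sum_{j=0..k} left^j (x) right^{k-j}, with the
    level-0 terms equal to 1.
    """
    depth = len(left)
    out = []
    for k in range(1, depth + 1):
        acc = left[k - 1] + right[k - 1]
        for j in range(1, k):
            acc = acc + np.multiply.outer(left[j - 1], right[k - j - 1])
        out.append(acc)
    return out


def compute_signature(path: np.ndarray, depth: int) -> SignatureFeature:
    """Exact truncated signature of the piecewise-linear path (tau x d).

    Computed by chaining each segment's tensor exponential with Chen's
    identity; no numerical quadrature is involved.
    """
    path = np.asarray(path, dtype=np.float64)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("path must be tau x d with tau >= 2")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    d = path.shape[1]
    if d**depth > _MAX_FEATURES:
        raise ValueError(
            f"signature would have {d**depth} level-{depth} entries; lower the depth"
        )
    increments = np.diff(path, axis=0)
    sig = _segment_levels(increments[0], depth)
    for delta in increments[1:]:
        sig = chen_product(sig, _segment_levels(delta, depth), d)
    return SignatureFeature(levels=sig, d=d, normalized=False)


def normalize_signature(sig: SignatureFeature) -> SignatureFeature:
    """Divide each level by its Euclidean norm (all-zero levels stay zero)."""
    levels = []
    for lvl in sig.levels:
        norm = float(np.linalg.norm(lvl))
        levels.append(lvl / norm if norm > 0 else lvl.copy())
    return SignatureFeature(levels=levels, d=sig.d, normalized=True)


def signature_features(
    traj: LatentTrajectory | np.ndarray,
    depth: int = 2,
    times: np.ndarray | None = None,
    standardize: bool = True,
    augment_time: bool = False,
) -> np.ndarray:
    """Full featurization: standardize -> rescale time -> signature -> normalize.

    Returns the flattened normalized levels 1..depth in fixed lexicographic
    order (length d + d^2 + ... + d^depth).  With ``augment_time`` the
    rescaled time is appended as an extra path coordinate before the
    signature is taken (off by default, matching the plain-path pipeline).
    """
    path = traj.states if isinstance(traj, LatentTrajectory) else np.asarray(traj)
    tau = path.shape[0]
    if times is None:
        times = np.arange(tau, dtype=np.float64)
    if standardize:
        path, _ = standardize_path(path, a=float(times[0]), b=float(times[-1]))
    t01 = rescale_time(times, float(times[0]), float(times[-1]))
    if augment_time:
        path = np.column_stack([path, t01])
    sig = compute_signature(path, depth)
    return normalize_signature(sig).flatten()
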