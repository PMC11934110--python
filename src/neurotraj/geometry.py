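"""3-D temporal diffusion embedding and curvature of latent trajectories.

``embed_trajectory`` maps a tau x d latent trajectory to 3-D with a
diffusion-based manifold embedding whose affinities combine feature-space
proximity (adaptive-bandwidth alpha-decay kernel) with temporal
autocorrelation (a Gaussian kernel over time lags whose width is set by the
trajectory's own autocorrelation decay).  The two row-stochastic operators
are averaged, diffused for t steps (t auto-selected by a von Neumann entropy
knee), and the log-potential distances are embedded by classical MDS.  The
construction is fully deterministic: eigendecompositions have fixed sign
conventions, so identical inputs give identical coordinates.

``curvature_profile`` estimates curvature pointwise by the local circle-fit
recipe: around each point take a symmetric neighborhood covering a fixed
fraction (default 8%) of the curve, center it, find the local plane by SVD,
project, fit a circle by least squares, and report kappa = 1/r.  The four
values at the task-switch times are the geometric features used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .autoencoder import LatentTrajectory
from .data_model import ParadigmTimeline

__all__ = [
    "EmbeddingParams",
    "EmbeddedTrajectory",
    "CurvatureProfile",
    "embed_trajectory",
    "curvature_profile",
    "switch_curvatures",
    "compare_curvature_groups",
    "fit_circle_2d",
]


@dataclass
class EmbeddingParams:
    n_components: int = 3
    knn: int = 5  # adaptive-bandwidth neighbor index
    bandwidth_scale: float = 3.0  # multiplier on the knn distance
    decay: float = 2.0  # alpha-decay exponent of the feature kernel
    temporal_weight: float = 0.25  # mixing weight of the temporal operator
    diffusion_time: int | None = None  # None -> auto via entropy knee
    max_diffusion_time: int = 20
    seed: int = 0  # surfaced for config completeness; embedding is deterministic


@dataclass
class EmbeddedTrajectory:
    coords: np.ndarray  # tau x 3
    times: np.ndarray  # block-local seconds, strictly increasing
    subject_id: str = "unknown"
    block_index: int = -1
    modality_pair: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedded coordinates contain non-finite values")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def tau(self) -> int:
        return self.coords.shape[0]


@dataclass
class CurvatureProfile:
    """Pointwise curvature along an embedded trajectory.

    ``kappa`` has one entry per trajectory point; boundary points whose
    symmetric neighborhood would have fewer than 4 usable neighbors are NaN
    and excluded from ``supported``.
    """

    kappa: np.ndarray
    supported: np.ndarray  # boolean mask of defined points
    switch_kappas: np.ndarray = field(default_factory=lambda: np.empty(0))
    neighborhood_fraction: float = 0.08


def _autocorr_width(X: np.ndarray, max_lag: int) -> int:
    """Lag at which the mean channel autocorrelation first drops below 1/e."""
    Xc = X - X.mean(axis=0)
    denom = (Xc**2).sum(axis=0)
    denom = np.where(denom == 0, 1.0, denom)
    for lag in range(1, max_lag):
        r = (Xc[:-lag] * Xc[lag:]).sum(axis=0) / denom
        if float(np.mean(r)) < np.exp(-1):
            return lag
    return max_lag


def _row_normalize(K: np.ndarray) -> np.ndarray:
    s = K.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return K / s


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic,
    stable under row permutations of the input data)."""
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def _auto_diffusion_time(P: np.ndarray, t_max: int) -> int:
    """Knee of the von Neumann entropy of the diffusion operator's spectrum."""
    lam = np.abs(np.linalg.eigvals(P))
    lam = np.sort(lam)[::-1]
    lam = lam[lam > 1e-12]
    ents = []
    for t in range(1, t_max + 1):
        p = lam**t
        p = p / p.sum()
        ents.append(float(-(p * np.log(p + 1e-300)).sum()))
    ents = np.asarray(ents)
    if len(ents) < 3:
        return 1
    # knee: largest distance below the chord from first to last entropy
    x = np.arange(len(ents), dtype=float)
    chord = ents[0] + (ents[-1] - ents[0]) * x / x[-1]
    return int(np.argmax(chord - ents)) + 1


def embed_trajectory(
    traj: LatentTrajectory | np.ndarray,
    params: EmbeddingParams | None = None,
    rate: float | None = None,
) -> EmbeddedTrajectory:
    """Embed a latent trajectory into 3-D, respecting temporal structure.

    ``rate`` sets the block-local time axis; by default it is inferred so
    the tau samples span one 30-s block.
    """
    params = params or EmbeddingParams()
    if isinstance(traj, LatentTrajectory):
        X = traj.states
        meta = dict(
            subject_id=traj.subject_id,
            block_index=traj.block_index,
            modality_pair=traj.modality_pair,
        )
    else:
        X = np.asarray(traj, dtype=np.float64)
        meta = {}
    tau = X.shape[0]
    if tau < 10:
        raise ValueError("trajectory too short to embed (need tau >= 10)")

    # feature kernel: adaptive-bandwidth alpha-decay
    D = squareform(pdist(X))
    sigma = params.bandwidth_scale * np.sort(D, axis=1)[:, min(params.knn, tau - 1)]
    sigma[sigma == 0] = np.min(sigma[sigma > 0], initial=1.0)
    K = np.exp(-((D / sigma[:, None]) ** params.decay))
    K = 0.5 * (K + K.T)

    # temporal kernel: width from the trajectory's autocorrelation decay
    w = max(1, _autocorr_width(X, max_lag=max(2, tau // 4)))
    lags = np.abs(np.subtract.outer(np.arange(tau), np.arange(tau)))
    T = np.exp(-0.5 * (lags / w) ** 2)

    tw = params.temporal_weight
    P = (1.0 - tw) * _row_normalize(K) + tw * _row_normalize(T)
    t = params.diffusion_time or _auto_diffusion_time(P, params.max_diffusion_time)
    Pt = np.linalg.matrix_power(P, t)

    # potential distances + classical MDS
    U = -np.log(Pt + 1e-12)
    G = squareform(pdist(U)) ** 2
    J = np.eye(tau) - np.ones((tau, tau)) / tau
    B = -0.5 * J @ G @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][: params.n_components]
    vals_top = np.clip(vals[order], 0.0, None)
    coords = _fix_signs(vecs[:, order]) * np.sqrt(vals_top)

    if rate is None:
        rate = tau / 30.0
    times = np.arange(tau) / rate
    return EmbeddedTrajectory(coords=coords, times=times, **meta)


def fit_circle_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (center, radius).

    Degenerate (collinear) point sets give an unbounded radius; callers cap
    it.  Solves ||p - c||^2 = r^2 linearized as 2 c.p + (r^2 - |c|^2) = |p|^2.
    """
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    rhs = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    center = sol[:2]
    r2 = sol[2] + center @ center
    radius = np.sqrt(r2) if r2 > 0 else np.inf
    return center, float(radius)


def curvature_profile(
    emb: EmbeddedTrajectory | np.ndarray,
    neighborhood_fraction: float = 0.08,
) -> CurvatureProfile:
    """Pointwise curvature by local SVD-plane circle fitting (kappa = 1/r)."""
    coords = emb.coords if isinstance(emb, EmbeddedTrajectory) else np.asarray(emb)
    tau = coords.shape[0]
    if not 0.0 < neighborhood_fraction < 0.5:
        raise ValueError("neighborhood_fraction must lie in (0, 0.5)")
    k = max(1, int(round(neighborhood_fraction * tau)))
    half = max(2, k // 2)
    diameter = float(np.max(pdist(coords))) if tau > 1 else 0.0
    cap_radius = 1e6 * max(diameter, 1e-12)

    kappa = np.full(tau, np.nan)
    supported = np.zeros(tau, dtype=bool)
    for p in range(tau):
        m = min(p, tau - 1 - p, half)
        if 2 * m < 4:  # fewer than 4 neighbors -> undefined at this point
            continue
        nbhd = coords[p - m : p + m + 1]
        centered = nbhd - nbhd.mean(axis=0)
        # local plane from the top two right singular vectors
        _, s, Vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] <= 1e-12 * max(s[0], 1e-300):  # collinear neighborhood
            kappa[p] = 0.0
            supported[p] = True
            continue
        plane = centered @ Vt[:2].T
        _, radius = fit_circle_2d(plane)
        kappa[p] = 0.0 if (not np.isfinite(radius) or radius > cap_radius) else 1.0 / radius
        supported[p] = True
    return CurvatureProfile(
        kappa=kappa, supported=supported, neighborhood_fraction=neighborhood_fraction
    )


def switch_curvatures(
    profile: CurvatureProfile,
    timeline: ParadigmTimeline,
    rate: float,
) -> np.ndarray:
    """Curvature at the four task-switch times (indices floor(t * rate)).

    An unsupported switch index falls back to the nearest supported point,
    with a warning.
    """
    idx_supported = np.flatnonzero(profile.supported)
    if len(idx_supported) == 0:
        raise ValueError("curvature profile has no supported points")
    out = []
    for t_switch in timeline.switch_times:
        i = int(np.floor(t_switch * rate))
        i = min(max(i, 0), len(profile.kappa) - 1)
        if not profile.supported[i]:
            j = int(idx_supported[np.argmin(np.abs(idx_supported - i))])
            warnings.warn(
                f"switch time {t_switch}s maps to unsupported index {i}; "
                f"using nearest supported index {j}",
                stacklevel=2,
            )
            i = j
        out.append(profile.kappa[i])
    values = np.asarray(out)
    profile.switch_kappas = values
    return values


def compare_curvature_groups(df: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests over the standard contrasts.

    ``df`` needs columns ``group`` (TD/FEP), ``gaze``, ``valence`` and
    ``kappa`` (one row per curvature observation).  Contrasts: TD vs FEP
    within each condition, direct vs diverted gaze within each group, and
    positive vs negative valence within each group.  Empty cells skip the
    contrast with a warning.
    """
    results = []

    def _test(name: str, a: np.ndarray, b: np.ndarray) -> None:
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"contrast '{name}' skipped: a group is (nearly) empty",
                          stacklevel=3)
            return
        res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        results.append(
            {"contrast": name, "U": float(res.statistic), "p": float(res.pvalue),
             "n1": len(a), "n2": len(b)}
        )

    for (val, gz), sub in df.groupby(["valence", "gaze"]):
        _test(
            f"TD vs FEP | {val}/{gz}",
            sub.loc[sub["group"] == "TD", "kappa"].to_numpy(),
            sub.loc[sub["group"] == "FEP", "kappa"].to_numpy(),
        )
    for grp, sub in df.groupby("group"):
        _test(
            f"direct vs diverted | {grp}",
            sub.loc[sub["gaze"] == "direct", "kappa"].to_numpy(),
            sub.loc[sub["gaze"] == "diverted", "kappa"].to_numpy(),
        )
        _test(
            f"positive vs negative | {grp}",
            sub.loc[sub["valence"] == "positive", "kappa"].to_numpy(),
            sub.loc[sub["valence"] == "negative", "kappa"].to_numpy(),
        )
    return pd.DataFrame(results)
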