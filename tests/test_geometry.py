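"""Embedding contracts and curvature oracles (circle, line, helix)."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from neurotraj.data_model import FNIRS_RATE, build_timeline
from neurotraj.geometry import (
    CurvatureProfile,
    EmbeddingParams,
    compare_curvature_groups,
    curvature_profile,
    embed_trajectory,
    switch_curvatures,
)


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return Q


class TestEmbedding:
    def _planted(self, seed=0, tau=150, noise=0.01):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, tau)
        base = np.column_stack([np.sin(2 * np.pi * t), np.cos(4 * np.pi * t), t])
        X = base @ rng.normal(size=(3, 128)) + noise * rng.normal(size=(tau, 128))
        return base, X

    def test_planted_subspace_rank_order_preserved(self):
        base, X = self._planted()
        emb = embed_trajectory(X)
        rho = spearmanr(pdist(base), pdist(emb.coords)).statistic
        assert rho > 0.8

    def test_temporal_smoothness_contract(self):
        _, X = self._planted(seed=1)
        emb = embed_trajectory(X)
        steps = np.linalg.norm(np.diff(emb.coords, axis=0), axis=1)
        D = squareform(pdist(emb.coords))
        iu = np.triu_indices(len(X), k=2)  # non-adjacent pairs
        assert steps.mean() < np.percentile(D[iu], 10)

    def test_deterministic(self):
        _, X = self._planted(seed=2)
        e1 = embed_trajectory(X, EmbeddingParams(seed=0))
        e2 = embed_trajectory(X, EmbeddingParams(seed=0))
        assert np.array_equal(e1.coords, e2.coords)

    def test_time_reversal_reverses_geometry(self):
        _, X = self._planted(seed=3)
        fwd = embed_trajectory(X)
        rev = embed_trajectory(X[::-1].copy())
        assert np.allclose(rev.coords[::-1], fwd.coords, atol=1e-8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            embed_trajectory(np.zeros((5, 8)))


class TestCurvature:
    @pytest.mark.parametrize("radius", [0.5, 1.0, 2.0, 5.0])
    def test_circle_oracle(self, radius):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        circle = np.column_stack(
            [radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)]
        )
        coords = circle @ _random_rotation(int(radius * 10)).T + 5.0
        prof = curvature_profile(coords, 0.08)
        kappa = prof.kappa[prof.supported]
        assert np.all(np.abs(kappa - 1.0 / radius) < 0.01 / radius)

    def test_line_has_zero_curvature(self):
        line = np.outer(np.linspace(0, 1, 100), [1.0, 2.0, -0.5])
        prof = curvature_profile(line, 0.08)
        assert np.allclose(prof.kappa[prof.supported], 0.0)

    def test_helix_closed_form(self):
        # helix (cos t, sin t, c t): kappa = R / (R^2 + c^2) = 0.8 for R=1, c=0.5
        t = np.linspace(0, 6 * np.pi, 500)
        helix = np.column_stack([np.cos(t), np.sin(t), 0.5 * t])
        prof = curvature_profile(helix, 0.08)
        kappa = prof.kappa[prof.supported]
        assert abs(kappa.mean() - 0.8) < 0.05 * 0.8

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(120, 3)).cumsum(axis=0)
        moved = coords @ _random_rotation(11).T + np.array([3.0, -2.0, 9.0])
        p1 = curvature_profile(coords, 0.08)
        p2 = curvature_profile(moved, 0.08)
        assert np.allclose(p1.kappa[p1.supported], p2.kappa[p2.supported], rtol=1e-8)

    def test_scaling_law(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(120, 3)).cumsum(axis=0)
        p1 = curvature_profile(coords, 0.08)
        p2 = curvature_profile(4.0 * coords, 0.08)
        assert np.allclose(p2.kappa[p2.supported], p1.kappa[p1.supported] / 4.0,
                           rtol=1e-8)

    def test_kappa_nonnegative_and_boundaries_excluded(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(60, 3)).cumsum(axis=0)
        prof = curvature_profile(coords, 0.1)
        assert np.all(prof.kappa[prof.supported] >= 0)
        assert not prof.supported[0] and not prof.supported[-1]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            curvature_profile(np.zeros((50, 3)), 0.7)


class TestSwitchCurvatures:
    def test_constant_profile(self):
        tl = build_timeline()
        n = 244
        prof = CurvatureProfile(kappa=np.full(n, 0.5), supported=np.ones(n, bool))
        vals = switch_curvatures(prof, tl, FNIRS_RATE)
        assert np.allclose(vals, 0.5)

    def test_fnirs_rate_switch_indices(self):
        tl = build_timeline()
        n = 244
        prof = CurvatureProfile(kappa=np.arange(n, dtype=float),
                                supported=np.ones(n, bool))
        vals = switch_curvatures(prof, tl, FNIRS_RATE)
        assert list(vals) == [32, 73, 105, 146]  # floor(t * 8.13)

    def test_unsupported_index_falls_back_with_warning(self):
        tl = build_timeline()
        n = 244
        supported = np.ones(n, bool)
        supported[146] = False
        kappa = np.arange(n, dtype=float)
        kappa[146] = np.nan
        prof = CurvatureProfile(kappa=kappa, supported=supported)
        with pytest.warns(UserWarning, match="nearest supported"):
            vals = switch_curvatures(prof, tl, FNIRS_RATE)
        assert vals[3] in (145, 147)


class TestGroupComparison:
    def _df(self, td, fep, gaze="direct", valence="positive"):
        rows = [{"group": "TD", "gaze": gaze, "valence": valence, "kappa": v} for v in td]
        rows += [{"group": "FEP", "gaze": gaze, "valence": valence, "kappa": v} for v in fep]
        return pd.DataFrame(rows)

    def test_identical_distributions_give_high_p(self):
        df = self._df([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 0.5])
        out = compare_curvature_groups(df)
        td_fep = out[out["contrast"].str.startswith("TD vs FEP")]
        assert (td_fep["p"] > 0.4).all()

    def test_separated_groups_give_extreme_u(self):
        df = self._df([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        out = compare_curvature_groups(df)
        row = out[out["contrast"].str.startswith("TD vs FEP")].iloc[0]
        assert row["U"] in (0.0, 9.0)  # all-ranks-separated: U = 0 or n1*n2
        assert row["p"] == pytest.approx(0.1, abs=0.01)  # 2/C(6,3) two-sided

    def test_mann_whitney_matches_exhaustive_enumeration(self):
        """U and p agree with a from-scratch enumeration of all rank splits."""
        from itertools import combinations

        rng = np.random.default_rng(0)
        a = rng.normal(size=5)
        b = rng.normal(size=4) + 0.5
        df = self._df(a, b)
        row = compare_curvature_groups(df)[lambda d: d["contrast"].str.startswith("TD")].iloc[0]
        # brute force: U statistic = #(pairs a_i > b_j); null by enumerating
        # all C(9,5) assignments of the pooled sample to group A
        pooled = np.concatenate([a, b])
        u_obs = sum(x > y for x in a for y in b)
        n = len(pooled)
        null_u = [
            sum(x > y for x in pooled[list(idx)]
                for y in np.delete(pooled, list(idx)))
            for idx in combinations(range(n), len(a))
        ]
        null_u = np.array(null_u)
        mean_u = len(a) * len(b) / 2
        p_exact = np.mean(np.abs(null_u - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        assert row["U"] in (u_obs, len(a) * len(b) - u_obs)
        assert row["p"] == pytest.approx(p_exact, abs=1e-9)

    def test_empty_group_skips_with_warning(self):
        df = self._df([1.0, 2.0], [])
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_curvature_groups(df)
        assert not any(out.get("contrast", pd.Series(dtype=str)).str.startswith("TD vs FEP")) \
            if len(out) else True
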