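"""Synthetic-cohort generator: invariants, determinism, degenerate closed forms."""

import numpy as np
import pytest

from neurotraj.data_model import FNIRS_RATE, Group, Modality, build_timeline
from neurotraj.evaluation import ClassifierSpec, run_loso
from neurotraj.synthetic import (
    SimulationConfig,
    double_gamma_hrf,
    generate_cohort,
    generate_session,
    load_cohort,
    segment_boxcar,
    write_cohort,
)


class TestSessionGeneration:
    def test_session_passes_all_block_invariants(self, mini_cohort):
        for session in mini_cohort:
            session.validate()  # 24 blocks, 6 per condition, shapes enforced
        s = mini_cohort[0]
        assert s.blocks[Modality.EEG][0].data.shape == (7680, 32)
        assert s.blocks[Modality.FNIRS][0].data.shape == (244, 134)
        assert s.blocks[Modality.FACEAU][0].data.shape == (244, 17)

    def test_same_seed_identical_different_seed_not(self):
        cfg = SimulationConfig(seed=5)
        a = generate_session(Group.FEP, "fep_x", cfg)
        b = generate_session(Group.FEP, "fep_x", cfg)
        c = generate_session(Group.FEP, "fep_x", SimulationConfig(seed=6))
        assert np.array_equal(a.blocks[Modality.EEG][0].data,
                              b.blocks[Modality.EEG][0].data)
        assert not np.array_equal(a.blocks[Modality.EEG][0].data,
                                  c.blocks[Modality.EEG][0].data)

    def test_noiseless_uncoupled_fnirs_is_pure_hrf_response(self):
        """With zero noise, zero coupling and zero transients, every fNIRS
        channel is proportional to the HRF convolved with the gaze boxcar."""
        cfg = SimulationConfig(
            noise_sd={"eeg": 0.0, "fnirs": 0.0, "faceau": 0.0},
            coupling_strength=0.0,
            amp_jitter_sd=0.0,
        )
        s = generate_session(Group.TD, "td_pure", cfg)
        tl = build_timeline()
        template = np.convolve(
            segment_boxcar(tl, FNIRS_RATE, "gaze"), double_gamma_hrf(FNIRS_RATE)
        )[:244]
        for blk in s.blocks[Modality.FNIRS][:4]:
            for ch in (0, 67, 133):
                y = blk.data[:, ch]
                ratio = y[np.abs(template) > 1e-6] / template[np.abs(template) > 1e-6]
                assert np.allclose(ratio, ratio[0], atol=1e-9)

    def test_noiseless_transientless_eeg_is_band_limited(self):
        """Zero noise + zero transient leaves only the oscillation mixture:
        spectral power outside the delta/theta/alpha bands is negligible."""
        cfg = SimulationConfig(
            noise_sd={"eeg": 0.0, "fnirs": 0.0, "faceau": 0.0},
            switch_transient_amp={"TD": 0.0, "FEP": 0.0},
        )
        s = generate_session(Group.TD, "td_osc", cfg)
        x = s.blocks[Modality.EEG][0].data[:, 0]
        freqs = np.fft.rfftfreq(len(x), 1 / 256.0)
        power = np.abs(np.fft.rfft(x)) ** 2
        in_band = ((freqs >= 0.4) & (freqs <= 3.1)) | \
                  ((freqs >= 3.9) & (freqs <= 7.1)) | \
                  ((freqs >= 7.9) & (freqs <= 13.1))
        assert power[~in_band].sum() / power.sum() < 0.01

    def test_faceau_nonnegative(self, mini_cohort):
        for blk in mini_cohort[0].blocks[Modality.FACEAU]:
            assert np.all(blk.data >= 0)

    def test_severity_scores_only_for_patients(self, mini_cohort):
        for s in mini_cohort:
            if s.group is Group.FEP:
                assert np.isfinite(s.gaf) and np.isfinite(s.panss_pos)
            else:
                assert np.isnan(s.gaf)

    def test_planted_severity_link_sign(self):
        """Across many patient draws, larger realized transient amplitude
        means lower GAF and higher PANSS-positive (the planted link)."""
        cfg = SimulationConfig(seed=3, amp_jitter_sd=0.5)
        gafs, panss = [], []
        for i in range(20):
            s = generate_session(Group.FEP, f"fep_{i}", cfg)
            gafs.append(s.gaf)
            panss.append(s.panss_pos)
        r = np.corrcoef(gafs, panss)[0, 1]
        assert r < 0  # GAF falls as PANSS-positive rises, via the shared amplitude

    def test_config_validation(self):
        with pytest.raises(ValueError, match="coupling"):
            SimulationConfig(coupling_strength=1.5).validate()
        with pytest.raises(ValueError, match=">= 0"):
            SimulationConfig(n_td=-1).validate()


class TestCohort:
    def test_default_cohort_is_19_td_plus_14_fep(self):
        cfg = SimulationConfig()
        assert (cfg.n_td, cfg.n_fep) == (19, 14)

    def test_cohort_composition_and_boundary(self):
        cohort = generate_cohort(SimulationConfig(n_td=0, n_fep=2, seed=1))
        assert len(cohort) == 2
        assert all(s.group is Group.FEP for s in cohort)

    def test_cohort_roundtrip_byte_identical(self, mini_cohort, tmp_path):
        write_cohort(mini_cohort, tmp_path / "a")
        back = load_cohort(tmp_path / "a")
        assert [s.subject_id for s in back] == [s.subject_id for s in mini_cohort]
        for s1, s2 in zip(mini_cohort, back):
            for mod in s1.blocks:
                for b1, b2 in zip(s1.blocks[mod], s2.blocks[mod]):
                    assert np.array_equal(b1.data, b2.data)


class TestHRF:
    def test_double_gamma_shape(self):
        h = double_gamma_hrf(10.0)
        t = np.arange(len(h)) / 10.0
        assert h.max() == 1.0
        assert 4.0 < t[np.argmax(h)] < 8.0  # peak near 6 s
        undershoot = h[(t > 10) & (t < 25)]
        assert undershoot.min() < 0  # late undershoot present
        assert abs(undershoot.min()) < 0.5  # small relative to the peak


class TestPlantedEffectPropagation:
    """End-to-end: planted generator knobs drive the downstream summaries."""

    def test_switch_curvature_monotone_in_transient_amplitude(self, joint_setup):
        """Raising the patient transient amplitude raises the mean
        switch-time curvature of patient trajectories (3 levels, fixed
        model so the comparison is paired across amplitude levels)."""
        import dataclasses

        import pandas as pd

        from neurotraj.data_model import Group
        from neurotraj.pipeline import compute_feature_sets

        model = joint_setup["model"]
        cfg = joint_setup["config"]
        base_sim = cfg.simulation
        means = []
        for amp in (1.0, 2.5, 4.0):
            sim = dataclasses.replace(base_sim,
                                      switch_transient_amp={"TD": 1.0, "FEP": amp})
            fep = [s for s in generate_cohort(sim) if s.group is Group.FEP]
            fs = compute_feature_sets(fep, model, cfg, band="delta")
            meta = pd.DataFrame(fs["meta"])
            kap = [float(fs["curvatures"][(r.subject_id, r.block_index)].mean())
                   for r in meta.itertuples()]
            means.append(float(pd.Series(kap).mean()))
        assert means[0] < means[1] < means[2]

    def test_joint_finals_at_least_as_separable_as_unimodal(self, joint_setup,
                                                            joint_loso):
        """Cross-modal latents classify at least as well as unimodal ones on
        a cohort whose class effect is expressed in both modalities."""
        from neurotraj.pipeline import compute_feature_sets, train_pair_model

        cfg = joint_setup["config"]
        cohort = joint_setup["cohort"]
        uni_model, _ = train_pair_model(cohort, cfg, ("fnirs", "fnirs"))
        uni_features = compute_feature_sets(cohort, uni_model, cfg)
        uni = run_loso(uni_features["finals"], joint_setup["labels"],
                       ClassifierSpec("mlp2_on_final_embedding", seed=7))
        assert joint_loso.overall_accuracy >= uni.overall_accuracy
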