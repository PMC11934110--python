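"""Encoder-decoder mechanics: gradients, causality, teacher forcing, training."""

import numpy as np
import pytest

from neurotraj.autoencoder import (
    EncoderDecoderConfig,
    LatentTrajectory,
    Seq2SeqModel,
    decode,
    encode,
    extract_trajectories,
    grid_search_autoencoder,
    load_model,
    save_model,
    train_autoencoder,
)


def _tiny_config(**kw):
    base = dict(input_dim=3, output_dim=2, tau_in=6, tau_out=5,
                n_layers_enc=2, n_layers_dec=2, latent_dim=4,
                epochs=3, batch_size=4, seed=0)
    base.update(kw)
    return EncoderDecoderConfig(**base)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        """Analytic BPTT gradients agree with central differences everywhere
        sampled — validates the entire encoder/decoder/projection chain."""
        model = Seq2SeqModel(_tiny_config())
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 6, 3))
        Y = rng.normal(size=(2, 5, 2))
        _, grads = model.loss_and_grads(X, Y)
        eps = 1e-5
        params = model.named_params()
        for name, p in params.items():
            flat = p.reshape(-1)
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = model.loss_and_grads(X, Y)
                flat[i] = orig - eps
                lm, _ = model.loss_and_grads(X, Y)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name].reshape(-1)[i]
                assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-7), name


class TestEncoder:
    def test_latent_trajectory_shape(self):
        model = Seq2SeqModel(_tiny_config(input_dim=5, tau_in=30, latent_dim=8))
        traj = encode(np.random.default_rng(0).normal(size=(30, 5)), model)
        assert traj.states.shape == (30, 8)
        assert np.array_equal(traj.final, traj.states[-1])

    def test_causality_prefix_invariance(self):
        """h_t sees only x_1..x_{t-1}: perturbing x at step t leaves all
        states up to and including index t unchanged (one-step input lag)."""
        model = Seq2SeqModel(_tiny_config(tau_in=10))
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 3))
        base = encode(x, model).states
        t_perturb = 6
        x2 = x.copy()
        x2[t_perturb] += 10.0
        pert = encode(x2, model).states
        assert np.array_equal(base[: t_perturb + 1], pert[: t_perturb + 1])
        assert not np.allclose(base[t_perturb + 1 :], pert[t_perturb + 1 :])

    def test_shape_mismatch_rejected(self):
        model = Seq2SeqModel(_tiny_config())
        with pytest.raises(ValueError, match="input_dim"):
            encode(np.zeros((6, 7)), model)

    def test_deterministic_given_weights(self):
        model = Seq2SeqModel(_tiny_config())
        x = np.random.default_rng(3).normal(size=(6, 3))
        assert np.array_equal(encode(x, model).states, encode(x, model).states)


class TestDecoder:
    def test_output_shape_cross_modal(self):
        model = Seq2SeqModel(_tiny_config(output_dim=4, tau_out=12))
        y = decode(np.zeros(4), model)
        assert y.shape == (12, 4)

    def test_inference_deterministic(self):
        model = Seq2SeqModel(_tiny_config())
        h = np.random.default_rng(4).normal(size=4)
        assert np.array_equal(decode(h, model), decode(h, model))

    def test_teacher_conditions_next_step(self):
        """In teacher mode, changing the teacher value at step t changes the
        prediction at step t+1 but not at step t (y_t sees y*_{t-1})."""
        model = Seq2SeqModel(_tiny_config())
        rng = np.random.default_rng(5)
        h = rng.normal(size=4)
        teacher = rng.normal(size=(5, 2))
        base = decode(h, model, teacher=teacher)
        teacher2 = teacher.copy()
        teacher2[2] += 5.0
        pert = decode(h, model, teacher=teacher2)
        assert np.allclose(base[: 3], pert[: 3])
        assert not np.allclose(base[3], pert[3])

    def test_teacher_shape_mismatch(self):
        model = Seq2SeqModel(_tiny_config())
        with pytest.raises(ValueError, match="teacher"):
            decode(np.zeros(4), model, teacher=np.zeros((5, 7)))

    def test_degenerate_zero_weights_constant_output(self):
        model = Seq2SeqModel(_tiny_config())
        for name, p in model.named_params().items():
            model.set_param(name, np.zeros_like(p))
        y = decode(np.zeros(4), model, teacher=np.zeros((5, 2)))
        assert np.allclose(y, y[0])


class TestTraining:
    def _pairs(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        # smooth low-dim targets: learnable structure
        t = np.linspace(0, 1, 15)
        pairs = []
        for _ in range(n):
            phase = rng.uniform(0, 2 * np.pi)
            x = np.column_stack([np.sin(2 * np.pi * t + phase),
                                 np.cos(2 * np.pi * t + phase),
                                 rng.normal(0, 0.1, 15)])
            pairs.append((x, x[:, :2]))
        return pairs

    def test_rmse_decreases(self):
        cfg = _tiny_config(tau_in=15, tau_out=15, input_dim=3, output_dim=2,
                           epochs=15, learning_rate=1e-2)
        _, history = train_autoencoder(self._pairs(), cfg)
        assert history[-1] < history[0]

    def test_seeded_runs_identical(self):
        cfg = _tiny_config(tau_in=15, tau_out=15, input_dim=3, output_dim=2, epochs=3)
        _, h1 = train_autoencoder(self._pairs(), cfg)
        _, h2 = train_autoencoder(self._pairs(), cfg)
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_autoencoder([], _tiny_config())

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        cfg = _tiny_config(tau_in=15, tau_out=15, input_dim=3, output_dim=2)
        pairs = self._pairs()
        bad = pairs[0][0].copy()
        bad[3, 1] = np.inf
        pairs[0] = (bad, pairs[0][1])
        with pytest.raises(FloatingPointError, match="loss"):
            train_autoencoder(pairs, cfg)

    def test_grid_search_returns_argmin(self):
        cfg = _tiny_config(tau_in=15, tau_out=15, input_dim=3, output_dim=2, epochs=4)
        best_cfg, _, table = grid_search_autoencoder(
            self._pairs(), cfg, learning_rates=(1e-2, 1e-3), weight_decays=(0.0, 1e-4)
        )
        best_key = min(table, key=table.get)
        assert (best_cfg.learning_rate, best_cfg.weight_decay) == best_key


class TestExtractionAndCheckpoints:
    def test_one_trajectory_per_block_with_provenance(self, mini_cohort):
        cfg = EncoderDecoderConfig(input_modality="fnirs", output_modality="fnirs",
                                   input_dim=134, output_dim=134,
                                   tau_in=244, tau_out=244,
                                   n_layers_enc=1, n_layers_dec=1, latent_dim=4)
        model = Seq2SeqModel(cfg)
        session = mini_cohort[0]
        trajs = extract_trajectories([session], model)
        assert len(trajs) == 24
        keys = {(t.subject_id, t.block_index) for t in trajs}
        assert len(keys) == 24  # provenance maps each trajectory to its block

    def test_empty_session_list(self):
        model = Seq2SeqModel(_tiny_config())
        assert extract_trajectories([], model) == []

    def test_missing_modality_raises(self, mini_cohort):
        cfg = _tiny_config()
        cfg.input_modality = "eeg"
        model = Seq2SeqModel(cfg)
        from neurotraj.data_model import Modality, SessionRecord

        s = mini_cohort[0]
        partial = SessionRecord(s.subject_id, s.group,
                                {Modality.FNIRS: s.blocks[Modality.FNIRS]})
        with pytest.raises(ValueError, match="eeg"):
            extract_trajectories([partial], model)

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = _tiny_config()
        model, _ = train_autoencoder(
            [(np.random.default_rng(0).normal(size=(6, 3)),
              np.random.default_rng(1).normal(size=(5, 2)))], cfg)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        x = np.random.default_rng(2).normal(size=(6, 3))
        assert np.array_equal(encode(x, model).states, encode(x, back).states)


class TestLatentTrajectoryType:
    def test_final_is_last_row_and_finite_enforced(self):
        states = np.random.default_rng(0).normal(size=(10, 4))
        traj = LatentTrajectory(states=states)
        assert np.array_equal(traj.final, states[-1])
        states[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            LatentTrajectory(states=states)
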