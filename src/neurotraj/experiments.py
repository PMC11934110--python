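"""Named verification experiments on synthetic cohorts.

These are the package's reproducibility workloads: each function builds a
synthetic condition, runs the relevant slice of the pipeline, and returns
the measured quantities.  The test suite and ``scripts/acceptance.py`` both
drive them, so the numbers they report are always recomputed from scratch.

Conditions
----------
* ``easy_simulation`` — the separability-ceiling case: strong patient
  transients (4.0 vs 1.0), low noise, coupling 0.5.  Used where a property
  needs headroom (block accuracy > 0.9, curvature contrasts).
* ``severity_simulation`` — moderate effects with wide per-subject amplitude
  jitter, so block probabilities vary across patients and the planted
  severity link is measurable.
* ``idiosyncratic_simulation`` — weak class effect but strong per-subject
  channel gains: the condition under which block-level random splits are
  optimistically biased relative to LOSO.
* ``translation_simulation`` — low-noise cohort for the cross-modal
  permuted-pairing control.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .autoencoder import EncoderDecoderConfig, evaluate_rmse, train_autoencoder
from .data_model import Group, Modality
from .evaluation import ClassifierSpec, run_loso, run_random_split
from .pipeline import PipelineConfig, block_transform, compute_feature_sets
from .synthetic import SimulationConfig, generate_cohort

__all__ = [
    "easy_simulation",
    "severity_simulation",
    "idiosyncratic_simulation",
    "translation_simulation",
    "smoke_pipeline_config",
    "cohort_labels",
    "permutation_null_accuracies",
    "translation_control",
    "switch_curvature_table",
    "curvature_amplitude_sweep",
]


def easy_simulation(n_td: int = 4, n_fep: int = 4, seed: int = 7) -> SimulationConfig:
    return SimulationConfig(
        n_td=n_td,
        n_fep=n_fep,
        seed=seed,
        switch_transient_amp={"TD": 1.0, "FEP": 4.0},
        noise_sd={"eeg": 0.3, "fnirs": 0.2, "faceau": 0.15},
        coupling_strength=0.5,
    )


def severity_simulation(seed: int = 13) -> SimulationConfig:
    return SimulationConfig(n_td=5, n_fep=8, seed=seed, amp_jitter_sd=0.4)


def idiosyncratic_simulation(seed: int = 17) -> SimulationConfig:
    return SimulationConfig(
        n_td=4,
        n_fep=4,
        seed=seed,
        switch_transient_amp={"TD": 1.8, "FEP": 2.2},
        subject_gain_sd=0.6,
    )


def translation_simulation(seed: int = 31) -> SimulationConfig:
    return SimulationConfig(
        n_td=3,
        n_fep=3,
        seed=seed,
        noise_sd={"eeg": 0.2, "fnirs": 0.1, "faceau": 0.05},
        coupling_strength=0.5,
    )


def smoke_pipeline_config(simulation: SimulationConfig, **kw) -> PipelineConfig:
    """Desk-scale pipeline settings used by the verification experiments."""
    base = dict(master_seed=simulation.seed, latent_dim=16, epochs=10, batch_size=16)
    base.update(kw)
    cfg = PipelineConfig(**base)
    cfg.simulation = simulation
    return cfg


def cohort_labels(cohort) -> dict[str, int]:
    return {s.subject_id: int(s.group is Group.FEP) for s in cohort}


def permutation_null_accuracies(
    features, labels, n_permutations: int = 8, seed: int = 3,
    head: str = "mlp2_on_final_embedding",
) -> list[float]:
    """LOSO accuracies under balanced label permutations (chance control)."""
    rng = np.random.default_rng(seed)
    subjects = sorted(labels)
    values = np.array([labels[s] for s in subjects])
    accs = []
    for rep in range(n_permutations):
        perm = dict(zip(subjects, rng.permutation(values)))
        res = run_loso(features, perm, ClassifierSpec(head, seed=seed + rep))
        accs.append(res.overall_accuracy)
    return accs


def translation_control(
    seed: int = 31, epochs: int = 60, downsample: int = 8, latent_dim: int = 16
) -> dict[str, float]:
    """Cross-modal translation vs a permuted-pairing control.

    Trains EEG -> faceAU models on matched and permuted block pairings and
    compares held-out free-running RMSE (the decoder driven by ``h_tau``
    alone, so the score reflects what the latent carries).  FaceAU targets
    are left on their raw amplitude scale: the planted cross-modal link is
    the shared per-block effect amplitude, which is expressed in the AU
    level from block onset.
    """
    sim = translation_simulation(seed)
    cohort = generate_cohort(sim)
    cfg = PipelineConfig(master_seed=seed)
    tf_eeg = block_transform(cfg, "eeg", "delta")
    pairs = []
    for s in cohort:
        for be, ba in zip(s.blocks[Modality.EEG], s.blocks[Modality.FACEAU]):
            pairs.append((tf_eeg(be)[::downsample], ba.data[::downsample]))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pairs))
    n_test = len(pairs) // 4
    train_idx, test_idx = idx[n_test:], idx[:n_test]
    train = [pairs[i] for i in train_idx]
    test = [pairs[i] for i in test_idx]
    tau_in, tau_out = train[0][0].shape[0], train[0][1].shape[0]
    ae_cfg = EncoderDecoderConfig(
        input_modality="eeg", output_modality="faceau",
        input_dim=train[0][0].shape[1], output_dim=train[0][1].shape[1],
        tau_in=tau_in, tau_out=tau_out,
        n_layers_enc=2, n_layers_dec=2, latent_dim=latent_dim,
        epochs=epochs, batch_size=16, seed=seed,
    )
    model_true, _ = train_autoencoder(train, ae_cfg)
    perm = rng.permutation(len(train))
    train_perm = [(train[i][0], train[perm[i]][1]) for i in range(len(train))]
    model_perm, _ = train_autoencoder(train_perm, ae_cfg)
    return {
        "true_rmse": evaluate_rmse(model_true, test, teacher=False),
        "permuted_rmse": evaluate_rmse(model_perm, test, teacher=False),
        "true_rmse_teacher": evaluate_rmse(model_true, test, teacher=True),
        "permuted_rmse_teacher": evaluate_rmse(model_perm, test, teacher=True),
    }


def switch_curvature_table(features: dict, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-block mean switch curvature with group/condition metadata."""
    out = meta.copy()
    out["kappa"] = [
        float(np.mean(features["curvatures"][(r.subject_id, r.block_index)]))
        for r in meta.itertuples()
    ]
    return out


def curvature_amplitude_sweep(
    model, cfg: PipelineConfig, amplitudes=(1.0, 2.5, 4.0), band: str | None = "delta"
) -> list[float]:
    """Mean FEP switch curvature at several planted transient amplitudes.

    The trained model is held fixed and only the patient amplitude is varied
    (all other per-subject draws identical), so the sweep is a paired
    comparison of the planted effect's downstream footprint.
    """
    means = []
    for amp in amplitudes:
        sim = dataclasses.replace(
            cfg.simulation, switch_transient_amp={"TD": 1.0, "FEP": float(amp)}
        )
        fep = [s for s in generate_cohort(sim) if s.group is Group.FEP]
        fs = compute_feature_sets(fep, model, cfg, band=band)
        meta = pd.DataFrame(fs["meta"])
        kap = [
            float(np.mean(fs["curvatures"][(r.subject_id, r.block_index)]))
            for r in meta.itertuples()
        ]
        means.append(float(np.mean(kap)))
    return means


def idiosyncrasy_split_comparison(seed: int = 17) -> dict[str, float]:
    """LOSO vs block-level random split on the idiosyncratic condition.

    Features are raw (unstandardized) downsampled fNIRS blocks, preserving
    the per-subject gain signature that makes random splits optimistic.
    """
    sim = idiosyncratic_simulation(seed)
    cohort = generate_cohort(sim)
    labels = cohort_labels(cohort)
    feats = {
        (b.subject_id, b.block_index): b.data[::8].reshape(-1)
        for s in cohort
        for b in s.blocks[Modality.FNIRS]
    }
    spec = ClassifierSpec("mlp_baseline", seed=seed)
    return {
        "loso_accuracy": run_loso(feats, labels, spec).overall_accuracy,
        "random_split_accuracy": run_random_split(feats, labels, spec, seed=seed),
    }
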