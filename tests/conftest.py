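"""Shared fixtures: synthetic cohorts and trained models.

Cohort generation and autoencoder training are the expensive steps, so they
are session-scoped and shared across test modules.  The named conditions
(planted-easy, severity, idiosyncratic) live in ``neurotraj.experiments``
and are also what ``scripts/acceptance.py`` reruns.
"""

import pandas as pd
import pytest

from neurotraj.data_model import Group
from neurotraj.evaluation import ClassifierSpec, predict_severity, run_loso
from neurotraj.experiments import (
    cohort_labels,
    easy_simulation,
    idiosyncratic_simulation,
    severity_simulation,
    smoke_pipeline_config,
)
from neurotraj.pipeline import compute_feature_sets, train_pair_model
from neurotraj.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def mini_cohort():
    """Small cohort at the default (study-condition) effect sizes."""
    return generate_cohort(SimulationConfig(n_td=2, n_fep=2, seed=11))


@pytest.fixture(scope="session")
def easy_cohort():
    return generate_cohort(easy_simulation())


@pytest.fixture(scope="session")
def easy_labels(easy_cohort):
    return cohort_labels(easy_cohort)


@pytest.fixture(scope="session")
def joint_setup(easy_cohort, easy_labels):
    """Joint (cross-modal fNIRS->EEG) model + features on the easy cohort."""
    cfg = smoke_pipeline_config(easy_simulation())
    model, history = train_pair_model(easy_cohort, cfg, ("fnirs", "eeg"), band="delta")
    features = compute_feature_sets(easy_cohort, model, cfg, band="delta")
    return {
        "config": cfg,
        "model": model,
        "history": history,
        "features": features,
        "labels": easy_labels,
        "cohort": easy_cohort,
        "meta": pd.DataFrame(features["meta"]),
    }


@pytest.fixture(scope="session")
def joint_loso(joint_setup):
    return run_loso(
        joint_setup["features"]["finals"],
        joint_setup["labels"],
        ClassifierSpec("mlp2_on_final_embedding", seed=7),
    )


@pytest.fixture(scope="session")
def severity_setup():
    """Moderate-effect cohort with jittered severity for score regression."""
    sim = severity_simulation()
    cfg = smoke_pipeline_config(sim)
    cohort = generate_cohort(sim)
    labels = cohort_labels(cohort)
    model, _ = train_pair_model(cohort, cfg, ("fnirs", "eeg"), band="delta")
    features = compute_feature_sets(cohort, model, cfg, band="delta")
    result = run_loso(features["finals"], labels,
                      ClassifierSpec("mlp2_on_final_embedding", seed=sim.seed))
    scores = {s.subject_id: {"gaf": s.gaf, "panss_pos": s.panss_pos,
                             "panss_neg": s.panss_neg}
              for s in cohort if s.group is Group.FEP}
    preds, corr = predict_severity(result, scores)
    return {"result": result, "preds": preds, "corr": corr, "cohort": cohort}


@pytest.fixture(scope="session")
def idiosyncratic_features():
    """Weak class effect + strong per-subject channel gains, raw fNIRS blocks.

    Raw (unstandardized) features keep the subject-identity signal that a
    block-level random split exploits."""
    from neurotraj.data_model import Modality

    cohort = generate_cohort(idiosyncratic_simulation())
    labels = cohort_labels(cohort)
    feats = {(b.subject_id, b.block_index): b.data[::8].reshape(-1)
             for s in cohort for b in s.blocks[Modality.FNIRS]}
    return feats, labels
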