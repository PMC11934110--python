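"""Classification heads, leave-one-subject-out protocol, and severity scores.

All classification is evaluated with leave-one-subject-out (LOSO)
cross-validation: every fold withholds all 24 blocks of one subject and
trains on everyone else, so no within-subject information leaks from train
to test.  (Random block-level splits look far better than they should,
because each subject's idiosyncratic signal appears on both sides of the
split; the package exposes such a split only as a cautionary comparison.)

Severity prediction follows the block-averaging design: the classifier's
per-block patient probabilities are averaged over each patient's 24 blocks
to give a predicted severity score, which is correlated with the clinical
scores (GAF, PANSS positive/negative) min-max normalized to [0, 1].  The
clinical scores are never seen during classifier training.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "LOSOResult",
    "run_loso",
    "run_random_split",
    "predict_severity",
    "run_baselines",
    "evaluate_report",
    "HEAD_HIDDEN_SIZES",
]

#: hidden-layer widths per head; an n-layer MLP has n-1 hidden layers plus
#: the softmax output layer
HEAD_HIDDEN_SIZES: dict[str, tuple[int, ...]] = {
    "mlp2_on_final_embedding": (64,),
    "mlp4_on_signatures": (512, 128, 32),
    "mlp3_on_curvatures": (32, 16),
    "mlp_baseline": (64,),
}


@dataclass
class ClassifierSpec:
    head: str = "mlp2_on_final_embedding"
    hidden_sizes: tuple[int, ...] | None = None
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.head not in (*HEAD_HIDDEN_SIZES, "svm_baseline"):
            raise ValueError(f"unknown head '{self.head}'")

    def resolved_hidden(self) -> tuple[int, ...]:
        if self.hidden_sizes is not None:
            return tuple(self.hidden_sizes)
        return HEAD_HIDDEN_SIZES[self.head]


@dataclass
class LOSOResult:
    """Per-block patient probabilities and accuracies from LOSO evaluation."""

    per_block: pd.DataFrame  # columns: subject_id, block_index, prob_fep, label, fold
    fold_subjects: list[str]

    @property
    def overall_accuracy(self) -> float:
        """Fraction of correctly classified blocks (primary metric)."""
        pred = (self.per_block["prob_fep"] > 0.5).astype(int)
        return float((pred == self.per_block["label"]).mean())

    @property
    def per_subject_accuracy(self) -> pd.Series:
        pred = (self.per_block["prob_fep"] > 0.5).astype(int)
        ok = pred == self.per_block["label"]
        return ok.groupby(self.per_block["subject_id"]).mean()

    @property
    def subject_majority_accuracy(self) -> float:
        """Secondary metric: majority vote over each subject's blocks."""
        g = self.per_block.groupby("subject_id")
        maj = (g["prob_fep"].mean() > 0.5).astype(int)
        labels = g["label"].first()
        return float((maj == labels).mean())


def _make_classifier(spec: ClassifierSpec, fold_seed: int):
    if spec.head == "svm_baseline":
        return SVC(kernel="rbf", probability=True, random_state=fold_seed)
    return MLPClassifier(
        hidden_layer_sizes=spec.resolved_hidden(),
        activation="relu",
        solver="adam",
        alpha=spec.weight_decay,
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        random_state=fold_seed,
    )


def _check_features(
    features_by_block: Mapping[tuple[str, int], np.ndarray],
    labels_by_subject: Mapping[str, int],
) -> tuple[list[str], dict[str, list[tuple[int, np.ndarray]]]]:
    subjects = sorted(labels_by_subject)
    by_subject: dict[str, list[tuple[int, np.ndarray]]] = {s: [] for s in subjects}
    for (sid, bidx), vec in features_by_block.items():
        if sid not in by_subject:
            raise ValueError(f"features reference unlabeled subject '{sid}'")
        by_subject[sid].append((bidx, np.asarray(vec, dtype=np.float64)))
    for s in subjects:
        by_subject[s].sort(key=lambda t: t[0])
    classes = {labels_by_subject[s] for s in subjects}
    if len(classes) < 2:
        raise ValueError("need at least two classes across subjects")
    return subjects, by_subject


def run_loso(
    features_by_block: Mapping[tuple[str, int], np.ndarray],
    labels_by_subject: Mapping[str, int],
    spec: ClassifierSpec | None = None,
) -> LOSOResult:
    """Leave-one-subject-out evaluation of a classifier head.

    ``features_by_block`` maps (subject_id, block_index) to a feature vector;
    ``labels_by_subject`` maps subject_id to 0 (TD) or 1 (FEP).  Each fold
    withholds one subject, retrains the head with a fold-local seed, and
    scores the withheld blocks.  The train/test block sets are asserted
    disjoint on every fold.
    """
    spec = spec or ClassifierSpec()
    spec.validate()
    subjects, by_subject = _check_features(features_by_block, labels_by_subject)
    rows = []
    for fold, test_subject in enumerate(subjects):
        train_subjects = [s for s in subjects if s != test_subject]
        train_labels = {labels_by_subject[s] for s in train_subjects}
        if len(train_labels) < 2:
            raise ValueError(
                f"fold {fold}: a class is absent from the training set"
            )
        X_train = np.vstack(
            [vec for s in train_subjects for _, vec in by_subject[s]]
        )
        y_train = np.concatenate(
            [[labels_by_subject[s]] * len(by_subject[s]) for s in train_subjects]
        )
        test_keys = {(test_subject, b) for b, _ in by_subject[test_subject]}
        train_keys = {(s, b) for s in train_subjects for b, _ in by_subject[s]}
        assert not test_keys & train_keys, "LOSO leakage: train/test blocks overlap"
        X_test = np.vstack([vec for _, vec in by_subject[test_subject]])

        scaler = StandardScaler().fit(X_train)
        clf = _make_classifier(spec, fold_seed=spec.seed + fold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            clf.fit(scaler.transform(X_train), y_train)
            probs = clf.predict_proba(scaler.transform(X_test))
        fep_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        for (bidx, _), p in zip(by_subject[test_subject], probs):
            rows.append(
                {
                    "subject_id": test_subject,
                    "block_index": bidx,
                    "prob_fep": float(p[fep_col]),
                    "label": labels_by_subject[test_subject],
                    "fold": fold,
                }
            )
    return LOSOResult(per_block=pd.DataFrame(rows), fold_subjects=subjects)


def run_random_split(
    features_by_block: Mapping[tuple[str, int], np.ndarray],
    labels_by_subject: Mapping[str, int],
    spec: ClassifierSpec | None = None,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> float:
    """Block-level random-split accuracy (cautionary comparison to LOSO).

    Blocks are shuffled regardless of subject, so each subject's idiosyncratic
    signal appears in both halves; the resulting accuracy is optimistically
    biased and should NOT be reported as generalization performance.
    """
    spec = spec or ClassifierSpec()
    spec.validate()
    subjects, by_subject = _check_features(features_by_block, labels_by_subject)
    keys = [(s, b) for s in subjects for b, _ in by_subject[s]]
    X = np.vstack([vec for s in subjects for _, vec in by_subject[s]])
    y = np.array([labels_by_subject[s] for s, _ in keys])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_test = max(1, int(round(test_fraction * len(keys))))
    test_idx, train_idx = order[:n_test], order[n_test:]
    scaler = StandardScaler().fit(X[train_idx])
    clf = _make_classifier(spec, fold_seed=spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(scaler.transform(X[train_idx]), y[train_idx])
        pred = clf.predict(scaler.transform(X[test_idx]))
    return float((pred == y[test_idx]).mean())


def predict_severity(
    loso_result: LOSOResult,
    scores_by_subject: Mapping[str, Mapping[str, float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict severity as each patient's mean block probability.

    Only FEP subjects (label 1) with finite clinical scores enter the
    correlations.  Scores are min-max normalized to [0, 1].  Returns
    (per-subject predictions, correlation table with Pearson and Spearman).
    """
    blocks = loso_result.per_block
    fep = blocks[blocks["label"] == 1]
    preds = fep.groupby("subject_id")["prob_fep"].mean().rename("predicted")
    rows = []
    score_names = sorted({k for v in scores_by_subject.values() for k in v})
    for name in score_names:
        pairs = [
            (preds[s], scores_by_subject[s][name])
            for s in preds.index
            if s in scores_by_subject
            and name in scores_by_subject[s]
            and np.isfinite(scores_by_subject[s][name])
        ]
        if len(pairs) < 3:
            warnings.warn(f"score '{name}': fewer than 3 scored subjects; "
                          "correlation undefined", stacklevel=2)
            rows.append({"score": name, "pearson_r": np.nan, "pearson_p": np.nan,
                         "spearman_r": np.nan, "spearman_p": np.nan, "n": len(pairs)})
            continue
        p_arr = np.array([p for p, _ in pairs])
        s_arr = np.array([s for _, s in pairs])
        rng_s = s_arr.max() - s_arr.min()
        s_norm = (s_arr - s_arr.min()) / rng_s if rng_s > 0 else np.zeros_like(s_arr)
        if np.std(p_arr) == 0 or np.std(s_norm) == 0:
            warnings.warn(f"score '{name}': degenerate variance; correlation "
                          "undefined", stacklevel=2)
            rows.append({"score": name, "pearson_r": np.nan, "pearson_p": np.nan,
                         "spearman_r": np.nan, "spearman_p": np.nan, "n": len(pairs)})
            continue
        pe = pearsonr(p_arr, s_norm)
        sp = spearmanr(p_arr, s_norm)
        rows.append(
            {"score": name, "pearson_r": float(pe.statistic), "pearson_p": float(pe.pvalue),
             "spearman_r": float(sp.statistic), "spearman_p": float(sp.pvalue),
             "n": len(pairs)}
        )
    return preds.reset_index(), pd.DataFrame(rows)


def flatten_blocks(
    blocks_by_key: Mapping[tuple[str, int], np.ndarray],
    downsample: int = 8,
) -> dict[tuple[str, int], np.ndarray]:
    """Downsample-and-flatten raw blocks into baseline feature vectors."""
    return {
        k: np.asarray(v, dtype=np.float64)[::downsample].reshape(-1)
        for k, v in blocks_by_key.items()
    }


def run_baselines(
    blocks_by_key: Mapping[tuple[str, int], np.ndarray],
    labels_by_subject: Mapping[str, int],
    downsample: int = 8,
    seed: int = 0,
) -> dict[str, LOSOResult]:
    """SVM (RBF) and stand-alone MLP baselines on flattened raw blocks.

    Runs the same LOSO folds as the representation-based heads (folds are
    determined by the sorted subject list, so paired comparisons are valid).
    """
    feats = flatten_blocks(blocks_by_key, downsample)
    out = {}
    for head in ("svm_baseline", "mlp_baseline"):
        out[head] = run_loso(feats, labels_by_subject,
                             ClassifierSpec(head=head, seed=seed))
    return out


def evaluate_report(
    results: Mapping[str, LOSOResult],
    correlations: Mapping[str, pd.DataFrame] | None = None,
    group_tests: Mapping[str, pd.DataFrame] | None = None,
    out_dir: str | Path | None = None,
    config: Mapping | None = None,
) -> dict[str, pd.DataFrame]:
    """Collect accuracies, correlations, and group tests into summary tables.

    Writes CSV + JSON under ``out_dir`` when given, tagged with a hash of the
    run configuration.
    """
    acc_rows = [
        {
            "representation": name,
            "block_accuracy": res.overall_accuracy,
            "subject_majority_accuracy": res.subject_majority_accuracy,
            "n_subjects": len(res.fold_subjects),
            "n_blocks": len(res.per_block),
        }
        for name, res in results.items()
    ]
    tables: dict[str, pd.DataFrame] = {"accuracy": pd.DataFrame(acc_rows)}
    if correlations:
        tables["correlations"] = pd.concat(
            [df.assign(representation=name) for name, df in correlations.items()],
            ignore_index=True,
        )
    if group_tests:
        tables["group_tests"] = pd.concat(
            [df.assign(representation=name) for name, df in group_tests.items()],
            ignore_index=True,
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg_hash = hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        summary = {"config_hash": cfg_hash}
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
            summary[name] = df.to_dict(orient="records")
        (out_dir / "report.json").write_text(json.dumps(summary, indent=2, default=float))
    return tables
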