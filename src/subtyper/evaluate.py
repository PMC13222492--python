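"""Cohort splitting, scoring, and the label-noise robustness harness.

Accuracy is always computed over *scored* samples only — predictions whose
confidence fell below the abstention threshold are counted separately as
filtered, never as errors. (173 correct of 175 scored is an accuracy of
0.989 even if more samples were filtered.)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from subtyper.data_io import CountMatrix, SampleTable
from subtyper.pipeline import PipelineConfig, predict_pipeline, train_pipeline
from subtyper.synthetic import permute_labels

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    n_total: int
    n_scored: int
    n_filtered: int
    n_correct: int
    accuracy: float | None            # None when nothing was scored
    per_class: pd.DataFrame           # precision / recall / F1 over scored samples
    confusion: pd.DataFrame           # true x predicted, scored samples only

    def __post_init__(self) -> None:
        assert self.n_scored + self.n_filtered == self.n_total
        assert self.accuracy is None or 0 <= self.accuracy <= 1


def patient_split(
    sample_table: SampleTable,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Patient-level split, stratified by each patient's modal subtype.

    All samples of a patient land on the same side. Subtypes with a single
    patient go to training (with a warning) so every trained class exists.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    t = sample_table.table
    patient_label = (
        t.groupby("patient_id")["label"]
        .agg(lambda s: s.mode().iloc[0])
        .rename("modal_label")
    )
    rng = np.random.default_rng(seed)
    train_patients: list[str] = []
    test_patients: list[str] = []
    for label, grp in patient_label.groupby(patient_label):
        patients = sorted(grp.index)
        if len(patients) == 1:
            warnings.warn(
                f"subtype {label!r} has a single patient; assigned to training",
                stacklevel=2,
            )
            train_patients += patients
            continue
        perm = rng.permutation(len(patients))
        n_train = int(round(train_fraction * len(patients)))
        n_train = min(max(n_train, 1), len(patients) - 1)
        train_patients += [patients[i] for i in perm[:n_train]]
        test_patients += [patients[i] for i in perm[n_train:]]
    train_set, test_set = set(train_patients), set(test_patients)
    train_ids = [s for s, p in zip(t["sample_id"], t["patient_id"]) if p in train_set]
    test_ids = [s for s, p in zip(t["sample_id"], t["patient_id"]) if p in test_set]
    return train_ids, test_ids


def score_predictions(predictions: pd.DataFrame, truth: pd.Series) -> EvaluationReport:
    """Score a predictions frame (sample_id, predicted_class, status)
    against true labels (indexed by sample id)."""
    missing = [s for s in predictions["sample_id"] if s not in truth.index]
    if missing:
        raise ValueError(f"predictions without truth labels: {missing[:5]}")
    preds = predictions.copy()
    preds["true_class"] = truth.loc[preds["sample_id"]].to_numpy()
    scored = preds[preds["status"] == "scored"]
    n_total = len(preds)
    n_scored = len(scored)
    n_filtered = n_total - n_scored
    n_correct = int((scored["predicted_class"] == scored["true_class"]).sum())
    accuracy = n_correct / n_scored if n_scored else None

    classes = sorted(set(preds["true_class"]) | set(preds["predicted_class"]))
    confusion = pd.crosstab(
        scored["true_class"], scored["predicted_class"], dropna=False
    ).reindex(index=classes, columns=classes, fill_value=0)
    rows = []
    for cls in classes:
        tp = confusion.loc[cls, cls]
        fp = confusion[cls].sum() - tp
        fn = confusion.loc[cls].sum() - tp
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if tp + fn else np.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if (tp + fp) and (tp + fn) and (precision + recall) > 0
            else (0.0 if (tp + fp) or (tp + fn) else np.nan)
        )
        rows.append((cls, precision, recall, f1))
    per_class = pd.DataFrame(rows, columns=["class", "precision", "recall", "f1"]).set_index("class")
    return EvaluationReport(
        n_total=n_total,
        n_scored=n_scored,
        n_filtered=n_filtered,
        n_correct=n_correct,
        accuracy=accuracy,
        per_class=per_class,
        confusion=confusion,
    )


def _train_and_score(
    counts: CountMatrix,
    sample_table: SampleTable,
    train_ids: list[str],
    test_ids: list[str],
    config: PipelineConfig,
    train_labels: np.ndarray | None = None,
) -> EvaluationReport:
    train_counts = counts.subset_samples(train_ids)
    table = sample_table.aligned_to(train_ids)
    if train_labels is not None:
        table = SampleTable(table.table.assign(label=train_labels))
    bundle, _ = train_pipeline(train_counts, table, config)
    preds = predict_pipeline(bundle, counts.subset_samples(test_ids))
    truth = sample_table.aligned_to(test_ids).table.set_index("sample_id")["label"]
    return score_predictions(preds, truth)


def noise_robustness_experiment(
    counts: CountMatrix,
    sample_table: SampleTable,
    config: PipelineConfig,
    levels: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50),
    reps: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    noise_class: str | None = None,
) -> pd.DataFrame:
    """Retrain under training-label noise; evaluate on the untouched test set.

    For each level x replicate, a fraction of *training* labels is permuted
    (all classes, or only ``noise_class``), the whole pipeline — transforms
    included — is refit, and accuracy over scored test samples is recorded.
    Relative accuracy divides by this split's 0%-noise baseline.
    """
    train_ids, test_ids = patient_split(sample_table, train_fraction, seed=seed)
    baseline = _train_and_score(counts, sample_table, train_ids, test_ids, config)
    if baseline.accuracy is None:
        raise ValueError("baseline run scored no samples")
    base_labels = sample_table.labels_for(train_ids)

    rows = [
        (0.0, 0, baseline.accuracy, 1.0, baseline.n_filtered / baseline.n_total,
         baseline.per_class["f1"].mean())
    ]
    for level in levels:
        for rep in range(reps):
            noise_seed = seed + 1000 * rep + int(level * 100)
            if noise_class is None:
                noisy, _ = permute_labels(base_labels, level, seed=noise_seed)
            else:
                # class-specific noise: mislabel a fraction of one class's
                # samples as other (randomly drawn) classes
                rng = np.random.default_rng(noise_seed)
                members = np.flatnonzero(base_labels == noise_class)
                k = int(round(level * members.size))
                chosen = rng.choice(members, size=k, replace=False) if k else []
                others = np.unique(base_labels[base_labels != noise_class])
                noisy = base_labels.copy()
                for i in chosen:
                    noisy[i] = rng.choice(others)
            report = _train_and_score(
                counts, sample_table, train_ids, test_ids, config, train_labels=noisy
            )
            acc = report.accuracy if report.accuracy is not None else np.nan
            rows.append(
                (
                    level,
                    rep,
                    acc,
                    acc / baseline.accuracy if acc == acc else np.nan,
                    report.n_filtered / report.n_total,
                    report.per_class["f1"].mean(),
                )
            )
            logger.info("noise %.0f%% rep %d: accuracy %.3f", level * 100, rep, acc)
    return pd.DataFrame(
        rows,
        columns=[
            "level", "rep", "accuracy", "relative_accuracy",
            "below_threshold_fraction", "mean_f1",
        ],
    )
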