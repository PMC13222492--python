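"""Bootstrap out-of-bag evaluation across candidate feature sets.

Candidate feature sets are PCA projections at a grid of variance-explained
targets (PCA65 ... PCA99) plus the top-k most variable genes. For each
bootstrap replicate the in-bag samples (drawn with replacement, same size
as the training set) carry the *entire* refit — quantile reference, batch
correction, PCA / variable-gene ranking, classifier — and the out-of-bag
samples are pushed through those frozen refits, so OOB accuracy is an
honest generalization estimate. Feature sets share bootstrap replicates,
which is what makes the paired t comparison between them valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from subtyper.classifier import ClassifierConfig, confidence, train_stacked
from subtyper.data_io import CountMatrix
from subtyper.frozen import (
    apply_fsva,
    apply_quantile_norm,
    fit_pca_at_variance,
    fit_quantile_reference,
    fit_sva,
    project_pca,
)


@dataclass
class BootstrapPlan:
    """300 replicates by default (organized as 30 batches x 10 models);
    reduced plans are used for desk-scale runs."""

    n_sets: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("need at least one bootstrap set")


@dataclass
class OOBResult:
    feature_set: str
    accuracies: np.ndarray          # per replicate; NaN where flagged
    flagged_replicates: list[int]   # replicates whose in-bag draw lost a class
    records: pd.DataFrame           # pooled OOB rows: replicate, sample_id, true_class, predicted_class, confidence, correct

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.nanstd(self.accuracies, ddof=1))


def draw_bootstrap(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """In-bag indices (with multiplicity, size n) and the untouched complement."""
    if n < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    in_bag = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), in_bag)
    return in_bag, oob


def bootstrap_draws(n: int, plan: BootstrapPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(plan.seed)
    return [draw_bootstrap(n, rng) for _ in range(plan.n_sets)]


def top_variable_genes(train_matrix: pd.DataFrame, k: int = 1000) -> list[str]:
    """Top-k genes by variance of the normalized, corrected training values.

    Ties break lexicographically by gene id for determinism.
    """
    if k > train_matrix.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {train_matrix.shape[0]}")
    variances = train_matrix.var(axis=1, ddof=1)
    order = sorted(train_matrix.index, key=lambda g: (-variances[g], g))
    return order[:k]


def _parse_feature_set(spec: str) -> tuple[str, float | int]:
    spec = spec.upper()
    if spec.startswith("PCA"):
        return "pca", float(spec[3:]) / 100.0
    if spec.startswith("TOP"):
        return "top", int(spec[3:])
    raise ValueError(f"unknown feature set spec {spec!r} (expected PCA<nn> or TOP<k>)")


def run_oob_evaluation(
    train_counts: CountMatrix,
    labels: np.ndarray,
    feature_sets: list[str],
    plan: BootstrapPlan,
    classifier_config: ClassifierConfig | None = None,
    n_sv: int | None = 0,
) -> dict[str, OOBResult]:
    """Per-replicate OOB accuracy for every candidate feature set.

    ``train_counts`` must already be restricted to the filtered gene
    universe. ``n_sv`` fixes the surrogate-variable count inside the
    replicate refits (None re-estimates each time).
    """
    labels = np.asarray(labels)
    n = train_counts.n_samples
    if classifier_config is None:
        classifier_config = ClassifierConfig()
    draws = bootstrap_draws(n, plan)
    parsed = {fs: _parse_feature_set(fs) for fs in feature_sets}
    sample_ids = np.array(train_counts.sample_ids)

    accuracies = {fs: np.full(plan.n_sets, np.nan) for fs in feature_sets}
    flagged: dict[str, list[int]] = {fs: [] for fs in feature_sets}
    rows: dict[str, list] = {fs: [] for fs in feature_sets}

    all_classes = np.unique(labels)
    for rep, (in_bag, oob) in enumerate(draws):
        if oob.size == 0:
            for fs in feature_sets:
                flagged[fs].append(rep)
            continue
        y_in = labels[in_bag]
        if np.unique(y_in).size < all_classes.size:
            for fs in feature_sets:
                flagged[fs].append(rep)
            continue
        in_counts = train_counts.counts.iloc[:, in_bag]
        in_counts.columns = [f"b{j}" for j in range(in_bag.size)]  # bootstraps repeat samples
        oob_counts = train_counts.counts.iloc[:, oob]

        try:
            ref = fit_quantile_reference(in_counts)
            norm_in = apply_quantile_norm(in_counts, ref)
            norm_oob = apply_quantile_norm(oob_counts, ref)
            sva = fit_sva(norm_in, y_in, n_sv=n_sv, seed=plan.seed + rep)
            corr_in = apply_fsva(norm_in, sva)
            corr_oob = apply_fsva(norm_oob, sva)
        except ValueError:
            for fs in feature_sets:
                flagged[fs].append(rep)
            continue

        y_oob = labels[oob]
        for fs, (kind, param) in parsed.items():
            try:
                if kind == "pca":
                    pca = fit_pca_at_variance(corr_in, param)
                    X_in = project_pca(corr_in, pca).to_numpy()
                    X_oob = project_pca(corr_oob, pca).to_numpy()
                else:
                    genes = top_variable_genes(corr_in, int(param))
                    X_in = corr_in.loc[genes].to_numpy().T
                    X_oob = corr_oob.loc[genes].to_numpy().T
                model = train_stacked(X_in, y_in, classifier_config)
            except ValueError:
                flagged[fs].append(rep)
                continue
            proba = model.predict_proba(X_oob)
            conf = confidence(proba)
            pred = np.array(model.classes)[proba.argmax(axis=1)]
            correct = pred == y_oob
            accuracies[fs][rep] = correct.mean()
            for sid, t, p, c, ok in zip(sample_ids[oob], y_oob, pred, conf, correct):
                rows[fs].append((rep, sid, t, p, float(c), bool(ok)))

    out = {}
    for fs in feature_sets:
        out[fs] = OOBResult(
            feature_set=fs,
            accuracies=accuracies[fs],
            flagged_replicates=flagged[fs],
            records=pd.DataFrame(
                rows[fs],
                columns=[
                    "replicate", "sample_id", "true_class",
                    "predicted_class", "confidence", "correct",
                ],
            ),
        )
    return out


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t test; a constant nonzero difference with zero
    variance yields (signed inf, p=0) by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    mask = ~np.isnan(d)
    d = d[mask]
    if d.size < 2:
        raise ValueError("need at least 2 paired replicates")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(d.size))
    p = 2 * stats.t.sf(abs(t), d.size - 1)
    return float(t), float(p)


def compare_feature_sets(results: dict[str, OOBResult], pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Paired t comparisons between feature sets sharing bootstrap draws,
    BH-adjusted across all requested pairs. Mirrors the selection table:
    feature sets, mean/SD accuracy, paired t, p, FDR p."""
    rows = []
    for fs1, fs2 in pairs:
        r1, r2 = results[fs1], results[fs2]
        if r1.accuracies.shape != r2.accuracies.shape:
            raise ValueError("replicate counts differ between feature sets")
        t, p = paired_t(r1.accuracies, r2.accuracies)
        rows.append(
            (fs1, fs2, r1.mean_accuracy, r1.sd_accuracy, r2.mean_accuracy, r2.sd_accuracy, t, p)
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "feature_set1", "feature_set2", "mean_acc1", "sd_acc1",
            "mean_acc2", "sd_acc2", "paired_t", "p",
        ],
    )
    frame["fdr_p"] = multipletests(frame["p"].fillna(1.0), method="fdr_bh")[1]
    return frame


def select_feature_set(results: dict[str, OOBResult], alpha: float = 0.05) -> str:
    """Smallest feature set not significantly worse than the best.

    'Smallest' means fewest features implied by the spec string (variance
    target ordering for PCA sets; TOP sets compare by k). Significance is a
    BH-adjusted paired t against the best-accuracy set.
    """
    best = max(results, key=lambda fs: results[fs].mean_accuracy)
    pairs = [(fs, best) for fs in results if fs != best]
    if not pairs:
        return best
    table = compare_feature_sets(results, pairs).set_index("feature_set1")

    def size_key(fs: str) -> float:
        kind, param = _parse_feature_set(fs)
        return param if kind == "pca" else 10.0 + param  # PCA targets < TOP k

    candidates = [best] + [
        fs for fs, _ in pairs
        if table.loc[fs, "fdr_p"] >= alpha or table.loc[fs, "paired_t"] > 0
    ]
    return min(candidates, key=size_key)
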