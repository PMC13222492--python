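"""End-to-end training and prediction orchestration.

``train_pipeline`` learns every frozen stage on the training cohort:

1. protocol-robust gene filter (defines the trained gene universe);
2. quantile reference, surrogate-variable correction, PCA projection;
3. the stacked ensemble on the PC scores;
4. abstention thresholds calibrated from pooled out-of-bag confidences of
   bootstrap refits (each refit re-learns the transforms on its in-bag
   draw, so the pooled confidences are honest);

and packs them into a :class:`~subtyper.data_io.ModelBundle`.
``predict_pipeline`` replays the frozen stages on query counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from subtyper.classifier import (
    ClassifierConfig,
    calibrate_thresholds,
    classify,
    confidence,
    predictions_frame,
    train_stacked,
)
from subtyper.data_io import CountMatrix, ModelBundle, SampleTable
from subtyper.feature_select import BootstrapPlan, bootstrap_draws
from subtyper.frozen import (
    apply_fsva,
    apply_quantile_norm,
    fit_pca_at_variance,
    fit_quantile_reference,
    fit_sva,
    project_pca,
)
from subtyper.gene_filter import GeneFilterConfig, apply_gene_filter

logger = logging.getLogger(__name__)

#: Deployed profile values: PCA variance target and OOB retention target.
PROFILES = {
    "ST": {"variance_target": 0.80, "retention_target": 0.95},
    "HM": {"variance_target": 0.85, "retention_target": 0.90},
}


@dataclass
class PipelineConfig:
    profile: str = "ST"
    variance_target: float | None = None
    retention_target: float | None = None
    minor_class_floor: float = 0.5
    gene_filter: GeneFilterConfig = field(default_factory=GeneFilterConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_sv: int | None = None
    threshold_bootstrap_sets: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in (*PROFILES, "custom"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile != "custom":
            defaults = PROFILES[self.profile]
            if self.variance_target is None:
                self.variance_target = defaults["variance_target"]
            if self.retention_target is None:
                self.retention_target = defaults["retention_target"]
        if self.variance_target is None or self.retention_target is None:
            raise ValueError("custom profile requires explicit variance and retention targets")


def collect_oob_confidences(
    filtered_counts: CountMatrix,
    labels: np.ndarray,
    config: PipelineConfig,
    n_sv: int,
) -> pd.DataFrame:
    """Pool OOB (replicate, sample, true class, prediction, confidence) rows
    over bootstrap refits of the transforms and classifier."""
    n = filtered_counts.n_samples
    plan = BootstrapPlan(n_sets=config.threshold_bootstrap_sets, seed=config.seed)
    draws = bootstrap_draws(n, plan)
    sample_ids = np.array(filtered_counts.sample_ids)
    rows = []
    for rep, (in_bag, oob) in enumerate(draws):
        if oob.size == 0:
            continue
        y_in = labels[in_bag]
        in_counts = filtered_counts.counts.iloc[:, in_bag]
        in_counts.columns = [f"b{j}" for j in range(in_bag.size)]
        oob_counts = filtered_counts.counts.iloc[:, oob]
        try:
            ref = fit_quantile_reference(in_counts)
            norm_in = apply_quantile_norm(in_counts, ref)
            norm_oob = apply_quantile_norm(oob_counts, ref)
            sva = fit_sva(norm_in, y_in, n_sv=n_sv, seed=config.seed + rep)
            corr_in = apply_fsva(norm_in, sva)
            corr_oob = apply_fsva(norm_oob, sva)
            pca = fit_pca_at_variance(corr_in, config.variance_target)
            model = train_stacked(
                project_pca(corr_in, pca).to_numpy(), y_in, config.classifier
            )
        except ValueError as exc:
            logger.warning("bootstrap replicate %d flagged: %s", rep, exc)
            continue
        proba = model.predict_proba(project_pca(corr_oob, pca).to_numpy())
        conf = confidence(proba)
        pred = np.array(model.classes)[proba.argmax(axis=1)]
        y_oob = labels[oob]
        for sid, t, p, c in zip(sample_ids[oob], y_oob, pred, conf):
            rows.append((rep, sid, t, p, float(c), bool(t == p)))
    return pd.DataFrame(
        rows,
        columns=["replicate", "sample_id", "true_class", "predicted_class", "confidence", "correct"],
    )


def train_pipeline(
    counts: CountMatrix,
    sample_table: SampleTable,
    config: PipelineConfig | None = None,
) -> tuple[ModelBundle, dict]:
    """Fit every stage on the training cohort; returns (bundle, report)."""
    if config is None:
        config = PipelineConfig()
    labels = sample_table.labels_for(counts.sample_ids)

    gf = apply_gene_filter(counts, sample_table, config.gene_filter)
    filtered = counts.subset_genes(gf.retained_genes)

    ref = fit_quantile_reference(filtered.counts)
    normalized = apply_quantile_norm(filtered.counts, ref)
    sva = fit_sva(normalized, labels, n_sv=config.n_sv, seed=config.seed)
    corrected = apply_fsva(normalized, sva)
    pca = fit_pca_at_variance(corrected, config.variance_target)
    scores = project_pca(corrected, pca)
    stacked = train_stacked(scores.to_numpy(), labels, config.classifier)

    oob_pool = collect_oob_confidences(filtered, labels, config, n_sv=sva.n_sv)
    if oob_pool.empty:
        raise ValueError("no out-of-bag confidences collected; cannot calibrate thresholds")
    thresholds = calibrate_thresholds(
        oob_pool[["confidence", "true_class"]],
        retention_target=config.retention_target,
        minor_class_floor=config.minor_class_floor,
    )

    bundle = ModelBundle(
        gene_filter=gf,
        quantile=ref,
        sva=sva,
        pca=pca,
        stacked=stacked,
        thresholds=thresholds,
        config={
            "profile": config.profile,
            "variance_target": config.variance_target,
            "retention_target": config.retention_target,
            "minor_class_floor": config.minor_class_floor,
            "n_sv": sva.n_sv,
            "threshold_bootstrap_sets": config.threshold_bootstrap_sets,
            "seed": config.seed,
            "gene_filter": asdict(config.gene_filter),
        },
    )
    report = {
        "n_genes_in": counts.n_genes,
        "n_genes_retained": len(gf.retained_genes),
        "exclusion_counts": pd.Series(list(gf.exclusion_reasons.values()))
        .value_counts()
        .to_dict(),
        "n_sv": sva.n_sv,
        "pca_k": pca.k,
        "classes": stacked.classes,
        "overall_threshold": thresholds.overall_threshold,
        "minor_classes": thresholds.minor_classes,
        "oob_pool": oob_pool,
        "oob_retained_fraction": float(
            (oob_pool["confidence"] >= thresholds.overall_threshold).mean()
        ),
    }
    return bundle, report


def transform_counts(bundle: ModelBundle, counts: CountMatrix) -> pd.DataFrame:
    """Frozen transforms only: counts -> PC scores (samples x k)."""
    filtered = counts.subset_genes(bundle.gene_filter.retained_genes)
    zero = filtered.counts.sum(axis=0) == 0
    if zero.any():
        warnings.warn(
            f"samples with zero counts over the trained gene set: "
            f"{list(filtered.counts.columns[zero])[:5]}",
            stacklevel=2,
        )
    normalized = apply_quantile_norm(filtered.counts, bundle.quantile)
    corrected = apply_fsva(normalized, bundle.sva)
    return project_pca(corrected, bundle.pca)


def predict_pipeline(bundle: ModelBundle, counts: CountMatrix) -> pd.DataFrame:
    """Frozen transforms + classifier + abstention on query counts."""
    scores = transform_counts(bundle, counts)
    preds = classify(
        bundle.stacked, bundle.thresholds, scores.to_numpy(), list(scores.index)
    )
    return predictions_frame(preds)
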