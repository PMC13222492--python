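"""Synthetic multi-subtype bulk RNA-seq cohort generator.

Counts are drawn from a negative-binomial (gamma-Poisson) model, the
standard overdispersed count model for bulk RNA-seq. The log2 mean of each
gene in each sample is composed of:

* a log-normal baseline expression level shared by all samples;
* a subtype expression program: each subtype adds a log2 effect on its own
  disjoint block of signature genes;
* a library-protocol capture bias: a random gene subset is shifted in
  poly(A) samples relative to total-RNA samples (what the gene filter is
  meant to remove);
* low-rank batch structure: rank-1 terms loading_g * factor_s, with the
  per-sample factor independent of subtype (what the surrogate-variable
  correction is meant to remove);
* a per-sample library-size factor (log-normal).

Every planted effect is recorded in :class:`GroundTruth`, so recovery
experiments for the filter, the batch correction, and the classifier can be
phrased purely against the generator output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from subtyper.data_io import CountMatrix, SampleTable


@dataclass
class SubtypeSpec:
    name: str
    n_samples: int
    n_signature_genes: int
    log2_effect: float


@dataclass
class SyntheticConfig:
    """Defaults describe a well-separated solid-tumor-like cohort:
    5 balanced subtypes, 60 samples each, 2000 genes, distinct expression
    programs, a 25%/75% poly(A)/total-RNA protocol mix with capture bias on
    5% of genes, and one rank-1 batch factor."""

    n_genes: int = 2000
    subtypes: list[SubtypeSpec] = field(
        default_factory=lambda: [
            SubtypeSpec(f"S{i + 1}", 60, 40, 2.0) for i in range(5)
        ]
    )
    protocol_effect_fraction: float = 0.05
    protocol_shift_log2: float = 3.0
    polya_fraction: float = 0.25
    n_batch_factors: int = 1
    batch_loading_scale: float = 0.4
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.25
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.05
    multi_sample_patient_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subtypes) < 2:
            raise ValueError("need at least 2 subtypes")
        if not (0 <= self.protocol_effect_fraction <= 1):
            raise ValueError("protocol_effect_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        total_sig = sum(s.n_signature_genes for s in self.subtypes)
        n_proto = int(round(self.protocol_effect_fraction * self.n_genes))
        if total_sig + n_proto > self.n_genes:
            raise ValueError(
                f"signature genes ({total_sig}) plus protocol-effect genes "
                f"({n_proto}) exceed n_genes ({self.n_genes})"
            )


def hm_like_config(seed: int = 0) -> SyntheticConfig:
    """A harder, hematologic-malignancy-like cohort: more subtypes with
    smaller, weaker expression programs, hence higher inter-class
    similarity."""
    return SyntheticConfig(
        subtypes=[SubtypeSpec(f"H{i + 1}", 40, 25, 1.0) for i in range(10)],
        seed=seed,
    )


@dataclass
class GroundTruth:
    signature_genes: dict[str, list[str]]
    protocol_genes: list[str]
    batch_factors: pd.DataFrame  # samples x n_batch_factors
    batch_loadings: pd.DataFrame  # genes x n_batch_factors
    labels: pd.Series  # sample_id -> subtype
    config: SyntheticConfig

    def to_json_dict(self) -> dict:
        return {
            "signature_genes": self.signature_genes,
            "protocol_genes": self.protocol_genes,
            "batch_factors": self.batch_factors.to_dict(orient="index"),
            "labels": self.labels.to_dict(),
            "config": {
                **{k: v for k, v in asdict(self.config).items() if k != "subtypes"},
                "subtypes": [asdict(s) for s in self.config.subtypes],
            },
        }


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    labels, sample_ids, patient_ids = [], [], []
    pat_counter = 0
    for spec in config.subtypes:
        n = spec.n_samples
        n_pairs = int(round(config.multi_sample_patient_fraction * n / 2.0))
        k = 0
        for _ in range(n_pairs):
            pat_counter += 1
            for rep in range(2):
                if k >= n:
                    break
                sample_ids.append(f"{spec.name}_s{k + 1:03d}")
                patient_ids.append(f"P{pat_counter:04d}")
                labels.append(spec.name)
                k += 1
        while k < n:
            pat_counter += 1
            sample_ids.append(f"{spec.name}_s{k + 1:03d}")
            patient_ids.append(f"P{pat_counter:04d}")
            labels.append(spec.name)
            k += 1
    n_samples = len(sample_ids)
    labels_arr = np.array(labels)

    protocols = np.where(
        rng.random(n_samples) < config.polya_fraction, "polyA", "totalRNA"
    )
    # the filter needs both groups represented
    if (protocols == "polyA").sum() < 2:
        protocols[:2] = "polyA"
    if (protocols == "totalRNA").sum() < 2:
        protocols[-2:] = "totalRNA"

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    log2_mu = np.tile(baseline[:, None], (1, n_samples))

    # disjoint subtype signature blocks, then protocol-effect genes from the rest
    perm = rng.permutation(config.n_genes)
    cursor = 0
    signature_genes: dict[str, list[str]] = {}
    for spec in config.subtypes:
        idx = perm[cursor : cursor + spec.n_signature_genes]
        cursor += spec.n_signature_genes
        signature_genes[spec.name] = [genes[i] for i in idx]
        cols = np.flatnonzero(labels_arr == spec.name)
        signs = rng.choice([-1.0, 1.0], size=idx.size)
        log2_mu[np.ix_(idx, cols)] += (signs * spec.log2_effect)[:, None]

    n_proto = int(round(config.protocol_effect_fraction * config.n_genes))
    proto_idx = perm[cursor : cursor + n_proto]
    protocol_genes = [genes[i] for i in proto_idx]
    polya_cols = np.flatnonzero(protocols == "polyA")
    if n_proto and config.protocol_shift_log2:
        signs = rng.choice([-1.0, 1.0], size=n_proto)
        log2_mu[np.ix_(proto_idx, polya_cols)] += (signs * config.protocol_shift_log2)[:, None]

    factors = rng.standard_normal((n_samples, config.n_batch_factors))
    loadings = rng.normal(0.0, config.batch_loading_scale, (config.n_genes, config.n_batch_factors))
    log2_mu += loadings @ factors.T

    libsize_factor = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n_samples)
    mu = np.exp2(log2_mu) * libsize_factor[None, :]
    counts = _nb_sample(rng, mu, config.nb_dispersion)

    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": patient_ids,
                "label": labels,
                "protocol": protocols,
                "cohort": "synthetic",
            }
        )
    )
    truth = GroundTruth(
        signature_genes=signature_genes,
        protocol_genes=protocol_genes,
        batch_factors=pd.DataFrame(
            factors, index=sample_ids,
            columns=[f"batch{i + 1}" for i in range(config.n_batch_factors)],
        ),
        batch_loadings=pd.DataFrame(
            loadings, index=genes,
            columns=[f"batch{i + 1}" for i in range(config.n_batch_factors)],
        ),
        labels=pd.Series(labels, index=sample_ids, name="label"),
        config=config,
    )
    return matrix, table, truth


def inject_protocol_effect(
    matrix: CountMatrix,
    sample_table: SampleTable,
    gene_subset: list[str],
    magnitude_log2: float,
    protocol: str = "polyA",
) -> CountMatrix:
    """Multiplicative 2**magnitude shift of ``gene_subset`` in samples of one protocol."""
    unknown = [g for g in gene_subset if g not in matrix.counts.index]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown[:5]}")
    if magnitude_log2 == 0:
        return CountMatrix(matrix.counts.copy())
    protocols = sample_table.protocols_for(matrix.sample_ids)
    cols = np.flatnonzero(protocols == protocol)
    out = matrix.counts.copy().astype(float)
    rows = out.index.get_indexer(gene_subset)
    out.iloc[rows, cols] = out.iloc[rows, cols] * (2.0 ** magnitude_log2)
    return CountMatrix(np.round(out).astype(np.int64))


def inject_batch_effect(
    matrix: CountMatrix,
    loadings: pd.Series,
    factor: pd.Series,
) -> CountMatrix:
    """Additive rank-1 term loadings x factor on the log2 scale (multiplicative on counts)."""
    unknown = [g for g in loadings.index if g not in matrix.counts.index]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown[:5]}")
    shift = np.zeros(matrix.counts.shape)
    rows = matrix.counts.index.get_indexer(loadings.index)
    cols = matrix.counts.columns.get_indexer(factor.index)
    shift[np.ix_(rows, cols)] = np.outer(loadings.to_numpy(), factor.to_numpy())
    out = matrix.counts.to_numpy() * np.exp2(shift)
    return CountMatrix(
        pd.DataFrame(
            np.round(out).astype(np.int64),
            index=matrix.counts.index,
            columns=matrix.counts.columns,
        )
    )


def permute_labels(
    labels: np.ndarray, fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Mislabel exactly round(fraction * n) samples.

    Each chosen sample's label is redrawn uniformly from the *other*
    classes, emulating label noise; returns (noisy labels, chosen indices).
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = labels.size
    k = int(round(fraction * n))
    idx = rng.choice(n, size=k, replace=False)
    classes = np.unique(labels)
    if classes.size < 2 and k > 0:
        raise ValueError("cannot permute labels with a single class")
    noisy = labels.copy()
    for i in idx:
        others = classes[classes != labels[i]]
        noisy[i] = rng.choice(others)
    return noisy, np.sort(idx)
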