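"""Protocol-robust gene filtering.

Bulk RNA-seq libraries prepared by poly(A) capture versus rRNA-depleted
total RNA measure a subset of genes systematically differently. Before any
frozen normalization is fit, the trained gene universe is restricted by a
multi-step filter:

1. low expression — drop genes whose maximum CPM over all samples is
   strictly below a floor (default 5);
2. protocol sensitivity — within each protocol group, per-gene expression
   is rank-transformed to percentiles; a gene is dropped if (a) its median
   percentile shifts by at least one quartile (>= 25 points) between
   protocols, (b) the 5th/95th percentile supports fail to overlap in
   either direction, or (c) at least 95% of cross-protocol value pairs are
   ordered the same way (either direction);
3. list-based removal — user-supplied exclusion lists (annotation-version
   -specific genes, histone genes) and an optional protein-coding
   restriction.

Each excluded gene records the first rule that fired, so the filter report
partitions the input gene set exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from subtyper.data_io import CountMatrix, SampleTable, DataValidationError

logger = logging.getLogger(__name__)

REASONS = (
    "low_expression",
    "shift",
    "no_overlap",
    "consistency",
    "annotation",
    "histone",
    "non_coding",
)


@dataclass
class GeneFilterConfig:
    cpm_floor: float = 5.0
    shift_threshold: float = 25.0
    low_tail: float = 5.0
    high_tail: float = 95.0
    consistency_fraction: float = 0.95
    exclusion_lists: dict[str, list[str]] = field(default_factory=dict)
    protein_coding_list: list[str] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.low_tail < self.high_tail < 100):
            raise ValueError("need 0 < low_tail < high_tail < 100")
        if not (0 < self.consistency_fraction <= 1):
            raise ValueError("consistency_fraction must be in (0, 1]")
        if self.cpm_floor <= 0:
            raise ValueError("cpm_floor must be positive")
        known = {"annotation", "histone"}
        unknown = set(self.exclusion_lists) - known
        if unknown:
            raise ValueError(f"unknown exclusion list names: {sorted(unknown)}")


@dataclass
class GeneFilterModel:
    """Outcome of the filter: retained gene vector plus per-gene exclusion reasons."""

    retained_genes: list[str]
    exclusion_reasons: dict[str, str]

    def report(self) -> pd.DataFrame:
        rows = [(g, "retained", "") for g in self.retained_genes]
        rows += [(g, "excluded", r) for g, r in self.exclusion_reasons.items()]
        return pd.DataFrame(rows, columns=["gene_id", "status", "reason"])

    def write_report(self, path: str | Path) -> None:
        self.report().to_csv(path, sep="\t", index=False)


def compute_cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: counts[g, s] / library_size[s] * 1e6."""
    libsize = counts.library_sizes()
    if (libsize <= 0).any():
        raise DataValidationError("zero library size")
    return counts.counts / libsize.to_numpy()[np.newaxis, :] * 1e6


def filter_low_expression(cpm: pd.DataFrame, config: GeneFilterConfig) -> set[str]:
    """Genes whose maximum CPM over all samples is strictly below the floor."""
    max_cpm = cpm.max(axis=1)
    return set(cpm.index[max_cpm < config.cpm_floor])


def rank_to_percentiles(values: np.ndarray) -> np.ndarray:
    """Map values to percentiles in [0, 100] via (rank-1)/(n-1)*100, mean ranks for ties."""
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples to rank")
    ranks = rankdata(values, method="average", axis=-1)
    return (ranks - 1.0) / (n - 1.0) * 100.0


def detect_protocol_sensitive(
    counts: CountMatrix,
    sample_table: SampleTable,
    config: GeneFilterConfig,
    cpm: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Per-gene first-firing reason among shift / no_overlap / consistency.

    Returns an empty mapping (with a warning) when only one protocol is
    present: the criteria compare protocol groups and are undefined with
    a single group.
    """
    protocols = sample_table.protocols_for(counts.sample_ids)
    groups = {p: np.flatnonzero(protocols == p) for p in np.unique(protocols)}
    if len(groups) < 2:
        warnings.warn(
            "single library protocol in cohort; protocol-sensitivity filter skipped",
            stacklevel=2,
        )
        return {}
    for p, idx in groups.items():
        if idx.size < 2:
            raise DataValidationError(f"protocol group {p!r} has fewer than 2 samples")

    if cpm is None:
        cpm = compute_cpm(counts)
    values = cpm.to_numpy()
    (pa_idx, pb_idx) = (groups[p] for p in sorted(groups))
    a = values[:, pa_idx]  # genes x nA
    b = values[:, pb_idx]

    # (a) median percentile shift >= threshold (inclusive). A gene's
    # percentile is its rank within each sample's expression distribution
    # (across genes); the per-gene median of those percentiles is compared
    # between protocol groups.
    pct_a = rank_to_percentiles(a.T).T  # rank across genes within each sample
    pct_b = rank_to_percentiles(b.T).T
    med_a = np.median(pct_a, axis=1)
    med_b = np.median(pct_b, axis=1)
    shift = np.abs(med_a - med_b) >= config.shift_threshold

    # (b) disjoint supports: 95th of one protocol strictly below 5th of the other
    lo_a = np.percentile(a, config.low_tail, axis=1)
    hi_a = np.percentile(a, config.high_tail, axis=1)
    lo_b = np.percentile(b, config.low_tail, axis=1)
    hi_b = np.percentile(b, config.high_tail, axis=1)
    no_overlap = (hi_a < lo_b) | (hi_b < lo_a)

    # (c) consistency: fraction of cross-protocol pairs ordered one way >= cutoff
    gt = (a[:, :, None] > b[:, None, :]).mean(axis=(1, 2))
    lt = (a[:, :, None] < b[:, None, :]).mean(axis=(1, 2))
    consistency = (gt >= config.consistency_fraction) | (lt >= config.consistency_fraction)

    reasons: dict[str, str] = {}
    for i, gene in enumerate(cpm.index):
        if shift[i]:
            reasons[gene] = "shift"
        elif no_overlap[i]:
            reasons[gene] = "no_overlap"
        elif consistency[i]:
            reasons[gene] = "consistency"
    return reasons


def apply_gene_filter(
    counts: CountMatrix,
    sample_table: SampleTable,
    config: GeneFilterConfig | None = None,
) -> GeneFilterModel:
    """Run the full filter; every input gene ends up retained or with one reason."""
    if config is None:
        config = GeneFilterConfig()
    cpm = compute_cpm(counts)
    reasons: dict[str, str] = {}

    for gene in filter_low_expression(cpm, config):
        reasons[gene] = "low_expression"

    survivors = [g for g in counts.gene_ids if g not in reasons]
    if survivors:
        sub = counts.subset_genes(survivors)
        proto = detect_protocol_sensitive(sub, sample_table, config, cpm=cpm.loc[survivors])
        reasons.update(proto)

    annotation = set(config.exclusion_lists.get("annotation", ()))
    histone = set(config.exclusion_lists.get("histone", ()))
    coding = set(config.protein_coding_list) if config.protein_coding_list is not None else None
    for gene in counts.gene_ids:
        if gene in reasons:
            continue
        if gene in annotation:
            reasons[gene] = "annotation"
        elif gene in histone:
            reasons[gene] = "histone"
        elif coding is not None and gene not in coding:
            reasons[gene] = "non_coding"

    retained = [g for g in counts.gene_ids if g not in reasons]
    if not retained:
        raise DataValidationError("gene filter excluded every gene")
    logger.info(
        "gene filter: %d retained, %d excluded (%s)",
        len(retained),
        len(reasons),
        pd.Series(list(reasons.values())).value_counts().to_dict(),
    )
    return GeneFilterModel(retained_genes=retained, exclusion_reasons=reasons)
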