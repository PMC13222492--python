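"""Count-matrix, metadata, and model-bundle I/O.

All joins between expression data and sample metadata are by sample id,
never by position, so files may list samples in any order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Library preparation protocols the scheme distinguishes.
PROTOCOLS = ("polyA", "totalRNA")

#: Prefix marking HTSeq-count summary rows (``__no_feature`` etc.).
HTSEQ_SUMMARY_PREFIX = "__"

BUNDLE_FORMAT_VERSION = 1


class DataValidationError(ValueError):
    """Raised when an input file or container violates the data model."""


@dataclass
class CountMatrix:
    """Integer gene x sample count table.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows (index = gene
        ids), samples as columns (columns = sample ids).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dups[:5]}")
        if c.size == 0:
            raise DataValidationError("count matrix is empty")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise DataValidationError("counts must be integers")
            self.counts = c.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise DataValidationError("counts must be non-negative")
        libsize = vals.sum(axis=0)
        if (libsize <= 0).any():
            bad = list(c.columns[libsize <= 0])
            raise DataValidationError(f"samples with zero library size: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        """Restrict to ``gene_ids`` (in the given order); missing genes are a hard error."""
        missing = [g for g in gene_ids if g not in self.counts.index]
        if missing:
            raise DataValidationError(
                f"{len(missing)} trained genes absent from the query matrix "
                f"(first few: {missing[:5]}); cannot apply frozen transforms"
            )
        return CountMatrix(self.counts.loc[list(gene_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise DataValidationError(f"unknown sample ids: {missing[:5]}")
        return CountMatrix(self.counts[list(sample_ids)])


@dataclass
class SampleTable:
    """Per-sample metadata: patient, subtype label, protocol, cohort."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "label", "protocol", "cohort")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise DataValidationError(f"sample table missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DataValidationError(f"duplicate sample ids in metadata: {dups[:5]}")
        bad = sorted(set(t["protocol"]) - set(PROTOCOLS))
        if bad:
            raise DataValidationError(
                f"unknown protocol values {bad}; expected one of {PROTOCOLS}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        """Rows for ``sample_ids`` in that order; every id must have a row."""
        t = self.table.set_index("sample_id", drop=False)
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise DataValidationError(f"samples without metadata rows: {missing[:5]}")
        return SampleTable(t.loc[list(sample_ids)].reset_index(drop=True))

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.aligned_to(sample_ids).table["label"].to_numpy()

    def protocols_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.aligned_to(sample_ids).table["protocol"].to_numpy()


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: gene filter, frozen
    transforms, classifier, and abstention thresholds, plus the config
    snapshot under which they were fit.

    The stages are only valid together: quantile reference, batch
    correction, and PCA are all defined on exactly the gene filter's
    retained gene vector.
    """

    gene_filter: object
    quantile: object
    sva: object
    pca: object
    stacked: object
    thresholds: object
    config: dict = field(default_factory=dict)
    format_version: int = BUNDLE_FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.gene_filter is not None and self.quantile is not None:
            n = len(self.gene_filter.retained_genes)
            if len(self.quantile.reference_means) != n:
                raise DataValidationError(
                    "quantile reference length does not match retained gene count"
                )


def read_htseq_counts(path: str | Path, sample_id: str) -> CountMatrix:
    """Read one HTSeq-count two-column file into a single-sample matrix.

    Summary rows (gene id starting with ``__``) are dropped; their totals
    are recorded in the QC log.
    """
    path = Path(path)
    genes: list[str] = []
    counts: list[int] = []
    summary_total = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataValidationError(
                    f"{path}:{lineno}: expected two TAB-separated fields, got {len(parts)}"
                )
            gene, raw = parts
            try:
                value = int(raw)
            except ValueError as exc:
                raise DataValidationError(
                    f"{path}:{lineno}: count {raw!r} is not an integer"
                ) from exc
            if value < 0:
                raise DataValidationError(f"{path}:{lineno}: negative count {value}")
            if gene.startswith(HTSEQ_SUMMARY_PREFIX):
                summary_total += value
                continue
            genes.append(gene)
            counts.append(value)
    if not genes:
        raise DataValidationError(f"{path}: no gene rows found")
    logger.info("%s: %d genes, %d reads in summary rows", path, len(genes), summary_total)
    frame = pd.DataFrame({sample_id: counts}, index=pd.Index(genes, name="gene_id"))
    return CountMatrix(frame)


def assemble_matrix(samples: Sequence[CountMatrix]) -> CountMatrix:
    """Column-bind single-sample matrices sharing one gene set.

    Gene order is canonicalized to the first sample's order; column order
    follows the input order.
    """
    if not samples:
        raise DataValidationError("no samples to assemble")
    first = samples[0]
    ref_genes = first.gene_ids
    ref_set = set(ref_genes)
    columns = [first.counts]
    for cm in samples[1:]:
        other = set(cm.gene_ids)
        if other != ref_set:
            diff = sorted(ref_set.symmetric_difference(other))
            raise DataValidationError(
                f"gene sets differ between samples; symmetric difference "
                f"({len(diff)} genes, first few): {diff[:10]}"
            )
        columns.append(cm.counts.loc[ref_genes])
    return CountMatrix(pd.concat(columns, axis=1))


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV (first column gene ids, header = sample ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise DataValidationError(f"{path}: no sample columns")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return CountMatrix(frame)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> SampleTable:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(table)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    payload = {
        "format_version": bundle.format_version,
        "bundle": bundle,
    }
    joblib.dump(payload, path)


def load_bundle(path: str | Path) -> ModelBundle:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise DataValidationError(
            f"bundle format version {version} not supported (expected {BUNDLE_FORMAT_VERSION})"
        )
    return payload["bundle"]
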