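"""Frozen preprocessing transforms.

Everything a query sample passes through at prediction time was learned
once, on the training cohort, and is applied unchanged afterwards:

* **quantile normalization** — counts are shifted by a pseudocount of 1 and
  log2-transformed; the reference distribution is the rank-wise mean of the
  sorted training columns. A new sample's values are replaced rank-wise by
  the reference (ties get the mean of the tied reference positions).
* **surrogate-variable batch correction** — latent factors (surrogate
  variables, SVs) orthogonal to the subtype design are estimated from the
  training residuals; the gene-space projection onto the SVs and the
  per-gene regression coefficients are frozen, so any sample (training or
  query) can be corrected by projecting onto the SVs and regressing them
  out. Training corrected profiles are *defined* as this frozen
  application, which makes train/apply consistency exact.
* **PCA** — components of the corrected training matrix; the component
  count k is the smallest whose cumulative explained variance reaches the
  configured target.

Matrices are genes x samples throughout (bioinformatics convention);
PC scores come back samples x k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

#: PCA variance-explained targets evaluated during feature selection.
VARIANCE_TARGET_GRID = (0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.99)

PSEUDOCOUNT = 1.0


def log2_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count + 1), the scale on which all frozen transforms operate."""
    return np.log2(counts + PSEUDOCOUNT)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


@dataclass
class QuantileReference:
    """Frozen target distribution: sorted rank-wise means of the training columns."""

    reference_means: np.ndarray  # non-decreasing, length = retained gene count
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.reference_means = np.asarray(self.reference_means, dtype=float)
        if np.any(np.diff(self.reference_means) < 0):
            raise ValueError("reference means must be non-decreasing")
        if len(self.reference_means) != len(self.gene_ids):
            raise ValueError("reference length must equal gene count")


def fit_quantile_reference(train_counts: pd.DataFrame) -> QuantileReference:
    """Learn the reference distribution from training counts (genes x samples)."""
    if train_counts.shape[1] < 2:
        raise ValueError("need at least 2 training samples for a quantile reference")
    logged = log2_counts(train_counts).to_numpy()
    ref = np.sort(logged, axis=0).mean(axis=1)
    return QuantileReference(reference_means=ref, gene_ids=list(train_counts.index))


def apply_quantile_norm(counts: pd.DataFrame, ref: QuantileReference) -> pd.DataFrame:
    """Map each sample's log2 values rank-wise onto the frozen reference.

    Tied input values receive the mean of the reference values at their
    tied ranks (implemented by interpolating fractional mean ranks).
    """
    if list(counts.index) != list(ref.gene_ids):
        raise ValueError(
            "gene vector of the input does not match the frozen reference "
            f"({counts.shape[0]} vs {len(ref.gene_ids)} genes)"
        )
    logged = log2_counts(counts).to_numpy()
    n = logged.shape[0]
    ranks = stats.rankdata(logged, method="average", axis=0)
    positions = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(logged)
    for j in range(logged.shape[1]):
        out[:, j] = np.interp(ranks[:, j], positions, ref.reference_means)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Surrogate variable analysis (frozen application)
# ---------------------------------------------------------------------------


@dataclass
class SVAModel:
    """Frozen batch-correction model.

    ``projection`` maps a centered gene-length profile to SV coordinates;
    ``coefficients`` are the per-gene regression slopes on the SVs, so
    correction is ``profile - coefficients @ sv``.
    """

    n_sv: int
    gene_ids: list[str]
    gene_means: np.ndarray          # training means used for centering, length genes
    projection: np.ndarray          # genes x n_sv
    coefficients: np.ndarray        # genes x n_sv
    classes: list[str] = field(default_factory=list)

    def surrogate_coords(self, profiles: np.ndarray) -> np.ndarray:
        """SV coordinates for profiles (genes x m) -> (m x n_sv)."""
        if self.n_sv == 0:
            return np.zeros((profiles.shape[1], 0))
        centered = profiles - self.gene_means[:, None]
        return centered.T @ self.projection


def _class_design(labels: np.ndarray) -> np.ndarray:
    classes, codes = np.unique(labels, return_inverse=True)
    design = np.zeros((labels.size, classes.size))
    design[np.arange(labels.size), codes] = 1.0
    return design


def estimate_n_sv(
    residuals: np.ndarray,
    design: np.ndarray | None = None,
    n_permutations: int = 20,
    quantile: float = 0.95,
    margin: float = 1.10,
    seed: int = 0,
) -> int:
    """Permutation (parallel-analysis style) count of non-noise components.

    Each permutation scrambles every gene column of the residual matrix
    independently, destroying cross-gene covariance while keeping the
    marginals; the permuted matrix is then re-residualized against the
    design so observed and null spectra share the same rank deficit.
    Leading components are kept while their singular value exceeds the
    permutation-null quantile of the same-index singular value by the
    relative ``margin``. The margin guards against the weak cross-gene
    coupling that quantile normalization itself induces (all samples share
    one value multiset), which lifts the whole leading spectrum by a couple
    of percent without any latent factor being present; genuine batch
    factors exceed the null severalfold.
    """
    rng = np.random.default_rng(seed)
    n, g = residuals.shape
    k_max = min(n, g) - 1
    observed = np.linalg.svd(residuals, compute_uv=False)[:k_max]
    null = np.empty((n_permutations, k_max))
    for b in range(n_permutations):
        # one permutation per column; vectorized via per-column argsort of noise
        order = np.argsort(rng.random((n, g)), axis=0)
        perm = np.take_along_axis(residuals, order, axis=0)
        if design is not None:
            beta = np.linalg.lstsq(design, perm, rcond=None)[0]
            perm = perm - design @ beta
        null[b] = np.linalg.svd(perm, compute_uv=False)[:k_max]
    cutoffs = np.quantile(null, quantile, axis=0) * margin
    n_sv = 0
    for i in range(k_max):
        if observed[i] > cutoffs[i]:
            n_sv += 1
        else:
            break
    return n_sv


def _design_weights(X: np.ndarray, design: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """Per-gene down-weighting of design-associated genes.

    Genes carrying the subtype signal must not drive surrogate-variable
    estimation: under label noise the class design absorbs that signal
    imperfectly and the residuals of signature genes align with the true
    biology, which a naive residual SVD would then remove. The weight is
    the per-gene p-value of the class-design F test (association with the
    design -> weight near 0; null genes -> roughly uniform weights), a
    single-pass version of iteratively re-weighted SV estimation.
    """
    n, k = design.shape
    sse = (residuals**2).sum(axis=0)
    sst = ((X - X.mean(axis=0)) ** 2).sum(axis=0)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((sst - sse) / df1) / (sse / df2)
    f = np.where(np.isfinite(f), f, np.inf)
    return stats.f.sf(f, df1, df2)


def fit_sva(
    normalized_train: pd.DataFrame,
    labels: np.ndarray,
    n_sv: int | None = None,
    seed: int = 0,
) -> SVAModel:
    """Estimate surrogate variables on the training matrix (genes x samples).

    The subtype design is regressed out and design-associated genes are
    down-weighted, so SVs capture latent structure orthogonal to the
    biology of interest; the SV directions come from an SVD of the
    weighted residuals. With ``n_sv=None`` the count is chosen by
    permutation; pass an integer to fix it.
    """
    labels = np.asarray(labels)
    X = normalized_train.to_numpy().T  # samples x genes
    n, g = X.shape
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit the batch-correction model")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    design = _class_design(labels)
    # residuals of the class-means model
    beta = np.linalg.lstsq(design, X, rcond=None)[0]
    residuals = X - design @ beta
    weights = _design_weights(X, design, residuals)
    weighted = residuals * weights[None, :]
    if n_sv is None:
        n_sv = estimate_n_sv(weighted, design=design, seed=seed)

    gene_means = X.mean(axis=0)
    if n_sv == 0:
        zeros = np.zeros((g, 0))
        return SVAModel(0, list(normalized_train.index), gene_means, zeros, zeros,
                        classes=list(classes))

    _, _, vt = np.linalg.svd(weighted, full_matrices=False)
    projection = weights[:, None] * vt[:n_sv].T  # genes x n_sv, in weighted gene space

    # frozen SV coordinates of the training samples
    sv_train = (X - gene_means) @ projection  # n x n_sv
    # per-gene regression of expression on SVs (with intercept)
    design_sv = np.column_stack([np.ones(n), sv_train])
    coef = np.linalg.lstsq(design_sv, X, rcond=None)[0]  # (1 + n_sv) x genes
    coefficients = coef[1:].T  # genes x n_sv
    return SVAModel(
        n_sv=n_sv,
        gene_ids=list(normalized_train.index),
        gene_means=gene_means,
        projection=projection,
        coefficients=coefficients,
        classes=list(classes),
    )


def apply_fsva(profiles: pd.DataFrame, model: SVAModel) -> pd.DataFrame:
    """Correct profiles (genes x samples) with the frozen SV model.

    Each sample is projected onto the frozen SV directions and the stored
    gene-wise SV effects are regressed out; with zero surrogate variables
    this is the identity.
    """
    if list(profiles.index) != list(model.gene_ids):
        raise ValueError("gene vector does not match the frozen batch-correction model")
    if model.n_sv == 0:
        return profiles.copy()
    X = profiles.to_numpy()
    sv = model.surrogate_coords(X)  # m x n_sv
    corrected = X - model.coefficients @ sv.T
    return pd.DataFrame(corrected, index=profiles.index, columns=profiles.columns)


# ---------------------------------------------------------------------------
# PCA feature reduction
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: np.ndarray                 # genes x k
    explained_variance_ratio: np.ndarray # length k
    gene_means: np.ndarray               # training centering means
    gene_ids: list[str]
    variance_target: float
    k: int


def fit_pca_at_variance(corrected_train: pd.DataFrame, variance_target: float) -> PCAModel:
    """PCA of the corrected training matrix, keeping the minimal k whose
    cumulative explained variance reaches ``variance_target``."""
    if not (0 < variance_target <= 1):
        raise ValueError("variance target must be in (0, 1]")
    X = corrected_train.to_numpy().T  # samples x genes
    pca = PCA(svd_solver="full", random_state=0)
    pca.fit(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    total = cumvar[-1]
    if variance_target > total + 1e-12:
        raise ValueError(
            f"variance target {variance_target} exceeds representable variance {total:.6f}"
        )
    k = int(np.searchsorted(cumvar, variance_target - 1e-12) + 1)
    return PCAModel(
        loadings=pca.components_[:k].T,
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
        gene_means=pca.mean_,
        gene_ids=list(corrected_train.index),
        variance_target=variance_target,
        k=k,
    )


def project_pca(profiles: pd.DataFrame, model: PCAModel) -> pd.DataFrame:
    """Project corrected profiles (genes x samples) -> PC scores (samples x k)."""
    if list(profiles.index) != list(model.gene_ids):
        raise ValueError("gene vector does not match the frozen PCA model")
    X = profiles.to_numpy().T
    scores = (X - model.gene_means) @ model.loadings
    return pd.DataFrame(
        scores,
        index=profiles.columns,
        columns=[f"PC{i + 1}" for i in range(model.k)],
    )


# ---------------------------------------------------------------------------
# PC-level statistics
# ---------------------------------------------------------------------------


def rank_pcs_anova(scores: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """One-way ANOVA of each PC's scores across subtype groups, BH-adjusted.

    Returns a frame indexed by PC with columns F, p, q, sorted by q then F.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    for gname in groups:
        if (labels == gname).sum() < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 samples")
    f_vals, p_vals = [], []
    for pc in scores.columns:
        samples = [scores.loc[labels == gname, pc].to_numpy() for gname in groups]
        f, p = stats.f_oneway(*samples)
        f_vals.append(f)
        p_vals.append(p)
    q_vals = multipletests(p_vals, method="fdr_bh")[1]
    out = pd.DataFrame({"F": f_vals, "p": p_vals, "q": q_vals}, index=scores.columns)
    return out.sort_values(["q", "p"])


def discriminating_pcs_ttest(
    scores: pd.DataFrame,
    labels: np.ndarray,
    strict_q: float = 1e-20,
    relaxed_q: float = 1e-15,
) -> tuple[list[str], bool]:
    """PCs separating two groups, two-stage FDR thresholds.

    Per-PC two-sample t tests, BH-adjusted across PCs; select q < strict_q,
    falling back to q < relaxed_q if none qualify. Returns (selected PCs,
    relaxed flag); the flag is also set when even the relaxed threshold
    selects nothing.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    a_mask, b_mask = labels == groups[0], labels == groups[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    p_vals = []
    for pc in scores.columns:
        _, p = stats.ttest_ind(
            scores.loc[a_mask, pc], scores.loc[b_mask, pc], equal_var=True
        )
        p_vals.append(p)
    q_vals = multipletests(p_vals, method="fdr_bh")[1]
    strict = [pc for pc, q in zip(scores.columns, q_vals) if q < strict_q]
    if strict:
        return strict, False
    relaxed = [pc for pc, q in zip(scores.columns, q_vals) if q < relaxed_q]
    return relaxed, True
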