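import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subtyper.frozen import (
    PSEUDOCOUNT,
    apply_fsva,
    apply_quantile_norm,
    discriminating_pcs_ttest,
    fit_pca_at_variance,
    fit_quantile_reference,
    fit_sva,
    project_pca,
    rank_pcs_anova,
)
from subtyper.gene_filter import apply_gene_filter
from subtyper.synthetic import SyntheticConfig, generate_cohort


def quantile_norm_oracle(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force frozen quantile normalization on log2(count+1).

    Reference = rank-wise mean of sorted columns; each column's values are
    replaced by the reference value at their (average, tie-split) rank.
    """
    logged = np.log2(counts + PSEUDOCOUNT)
    ref = np.sort(logged, axis=0).mean(axis=1)
    out = np.empty_like(logged)
    n = logged.shape[0]
    for j in range(logged.shape[1]):
        ranks = stats.rankdata(logged[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return ref, out


def _frame(arr, prefix="G"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i + 1}" for i in range(arr.shape[0])],
        columns=[f"S{j + 1}" for j in range(arr.shape[1])],
    )


@pytest.fixture(scope="module")
def batch_cohort():
    """Generated cohort with one planted batch factor, filtered and normalized."""
    cfg = SyntheticConfig(seed=0)
    counts, table, truth = generate_cohort(cfg)
    gf = apply_gene_filter(counts, table)
    filt = counts.subset_genes(gf.retained_genes)
    labels = table.labels_for(filt.sample_ids)
    ref = fit_quantile_reference(filt.counts)
    norm = apply_quantile_norm(filt.counts, ref)
    return norm, labels, truth, filt


class TestQuantileNormalization:
    def test_identical_columns_reference_is_sorted_column(self):
        col = np.array([4, 1, 9])
        frame = _frame(np.column_stack([col, col]))
        ref = fit_quantile_reference(frame)
        np.testing.assert_allclose(
            ref.reference_means, np.sort(np.log2(col + 1))
        )

    def test_toy_matrix_matches_oracle(self):
        arr = np.array([[1, 3], [5, 7], [9, 11]])
        frame = _frame(arr)
        ref = fit_quantile_reference(frame)
        oracle_ref, oracle_out = quantile_norm_oracle(arr)
        np.testing.assert_allclose(ref.reference_means, oracle_ref, atol=1e-12)
        out = apply_quantile_norm(frame, ref)
        np.testing.assert_allclose(out.to_numpy(), oracle_out, atol=1e-12)

    def test_reference_length_equals_gene_count(self):
        frame = _frame(np.arange(12).reshape(4, 3))
        assert len(fit_quantile_reference(frame).reference_means) == 4

    def test_sample_distributed_as_reference_is_fixed_point(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 100, size=(8, 3))
        frame = _frame(arr)
        ref = fit_quantile_reference(frame)
        normed = apply_quantile_norm(frame, ref)
        again = normed.copy()
        # re-ranking the already-normalized values maps them to themselves
        ranks = stats.rankdata(again.to_numpy(), method="average", axis=0)
        remapped = np.stack(
            [
                np.interp(ranks[:, j], np.arange(1, 9), ref.reference_means)
                for j in range(3)
            ],
            axis=1,
        )
        np.testing.assert_allclose(remapped, normed.to_numpy(), atol=1e-12)

    def test_all_samples_share_sorted_values(self):
        rng = np.random.default_rng(1)
        arr = rng.permuted(np.tile(np.arange(10), (4, 1)).T, axis=0)
        out = apply_quantile_norm(_frame(arr), fit_quantile_reference(_frame(arr)))
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_length_mismatch_rejected(self):
        ref = fit_quantile_reference(_frame(np.arange(6).reshape(3, 2)))
        with pytest.raises(ValueError, match="gene vector"):
            apply_quantile_norm(_frame(np.arange(8).reshape(4, 2)), ref)

    def test_single_training_sample_rejected(self):
        with pytest.raises(ValueError, match="2 training samples"):
            fit_quantile_reference(_frame([[1], [2]]))


class TestSVA:
    def test_no_batch_structure_estimates_zero_svs(self):
        cfg = SyntheticConfig(n_batch_factors=0, seed=5)
        counts, table, _ = generate_cohort(cfg)
        gf = apply_gene_filter(counts, table)
        filt = counts.subset_genes(gf.retained_genes)
        norm = apply_quantile_norm(filt.counts, fit_quantile_reference(filt.counts))
        model = fit_sva(norm, table.labels_for(filt.sample_ids), seed=0)
        assert model.n_sv == 0
        corrected = apply_fsva(norm, model)
        pd.testing.assert_frame_equal(corrected, norm)

    def test_planted_batch_factor_recovered(self, batch_cohort):
        norm, labels, truth, filt = batch_cohort
        model = fit_sva(norm, labels, seed=0)
        assert model.n_sv >= 1
        sv = model.surrogate_coords(norm.to_numpy())
        planted = truth.batch_factors.loc[norm.columns, "batch1"].to_numpy()
        r = np.corrcoef(sv[:, 0], planted)[0, 1]
        assert abs(r) >= 0.9

    def test_correction_suppresses_batch_correlation(self, batch_cohort):
        norm, labels, truth, filt = batch_cohort
        model = fit_sva(norm, labels, seed=0)
        corrected = apply_fsva(norm, model)
        planted = truth.batch_factors.loc[norm.columns, "batch1"].to_numpy()
        X = corrected.to_numpy()
        cors = np.abs(
            [np.corrcoef(X[i], planted)[0, 1] for i in range(0, X.shape[0], 11)]
        )
        assert np.nanmean(cors) <= 0.1

    def test_frozen_consistency_on_training_samples(self, batch_cohort):
        norm, labels, _, _ = batch_cohort
        model = fit_sva(norm, labels, seed=0)
        # reapplying the frozen model to the training set is bit-identical
        full = apply_fsva(norm, model)
        again = apply_fsva(norm, model)
        np.testing.assert_array_equal(full.to_numpy(), again.to_numpy())
        # a single training sample corrected alone matches its in-batch
        # profile to floating-point accumulation accuracy
        one = apply_fsva(norm.iloc[:, [4]], model)
        np.testing.assert_allclose(
            one.to_numpy(), full.iloc[:, [4]].to_numpy(), atol=1e-9
        )

    def test_single_class_rejected(self):
        frame = _frame(np.arange(20).reshape(4, 5))
        with pytest.raises(ValueError, match="2 classes"):
            fit_sva(frame, np.array(["A"] * 5))

    def test_correction_does_not_hurt_class_separability(self, batch_cohort):
        """With batch independent of class, removing it must not reduce a
        simple classifier's cross-validated accuracy."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.model_selection import cross_val_score

        norm, labels, _, _ = batch_cohort
        model = fit_sva(norm, labels, seed=0)
        corrected = apply_fsva(norm, model)
        pca_before = fit_pca_at_variance(norm, 0.8)
        pca_after = fit_pca_at_variance(corrected, 0.8)
        acc_before = cross_val_score(
            LinearDiscriminantAnalysis(),
            project_pca(norm, pca_before).to_numpy(), labels, cv=3,
        ).mean()
        acc_after = cross_val_score(
            LinearDiscriminantAnalysis(),
            project_pca(corrected, pca_after).to_numpy(), labels, cv=3,
        ).mean()
        assert acc_after >= acc_before - 1e-12


class TestPCA:
    def _constructed_spectrum(self):
        # eigenvalue shares exactly (0.5, 0.3, 0.2) via scaled orthogonal scores
        rng = np.random.default_rng(0)
        n, g = 40, 6
        basis, _ = np.linalg.qr(rng.normal(size=(n, 3)))
        load, _ = np.linalg.qr(rng.normal(size=(g, 3)))
        scores = basis * np.sqrt(np.array([0.5, 0.3, 0.2]) * n)
        X = scores @ load.T
        X -= X.mean(axis=0)
        return pd.DataFrame(
            X.T, index=[f"G{i}" for i in range(g)], columns=[f"S{j}" for j in range(n)]
        )

    def test_k_follows_minimality_rule(self):
        frame = self._constructed_spectrum()
        assert fit_pca_at_variance(frame, 0.80).k == 2
        assert fit_pca_at_variance(frame, 0.85).k == 3

    def test_target_one_keeps_full_rank(self):
        frame = self._constructed_spectrum()
        model = fit_pca_at_variance(frame, 1.0)
        assert model.k == 3
        cumvar = np.cumsum(model.explained_variance_ratio)
        assert cumvar[-1] >= 1.0 - 1e-9

    def test_projection_reproduces_fit_scores(self, batch_cohort):
        norm, labels, _, _ = batch_cohort
        model = fit_pca_at_variance(norm, 0.8)
        scores_a = project_pca(norm, model)
        scores_b = project_pca(norm.iloc[:, :10], model)
        np.testing.assert_allclose(
            scores_a.iloc[:10].to_numpy(), scores_b.to_numpy(), atol=1e-9
        )

    def test_cumvar_minimality_invariant(self, batch_cohort):
        norm, _, _, _ = batch_cohort
        model = fit_pca_at_variance(norm, 0.8)
        full = fit_pca_at_variance(norm, 1.0 - 1e-12)
        cumvar = np.cumsum(full.explained_variance_ratio)
        assert cumvar[model.k - 1] >= 0.8
        assert model.k == 1 or cumvar[model.k - 2] < 0.8

    def test_unreachable_target_rejected(self):
        frame = self._constructed_spectrum()
        with pytest.raises(ValueError, match="target"):
            fit_pca_at_variance(frame, 1.5)


class TestPCStatistics:
    def test_null_pc_has_f_near_zero(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            {
                "PC1": np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30)]),
                "PC2": np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)]),
            }
        )
        labels = np.array(["A"] * 30 + ["B"] * 30)
        table = rank_pcs_anova(scores, labels)
        assert table.loc["PC2", "q"] < 1e-10
        assert table.loc["PC1", "q"] > 0.05
        assert table.index[0] == "PC2"

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        scores = pd.DataFrame({"PC1": np.concatenate([a, b])})
        labels = np.array(["A"] * 12 + ["B"] * 15)
        table = rank_pcs_anova(scores, labels)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        np.testing.assert_allclose(table.loc["PC1", "F"], t**2, rtol=1e-10)

    def test_singleton_group_rejected(self):
        scores = pd.DataFrame({"PC1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            rank_pcs_anova(scores, np.array(["A", "A", "B"]))

    def test_strongly_separated_pc_selected_at_strict_threshold(self):
        rng = np.random.default_rng(2)
        n = 200
        sep = np.concatenate([rng.normal(0, 1, n), rng.normal(20, 1, n)])
        noise = rng.normal(size=2 * n)
        scores = pd.DataFrame({"PC1": sep, "PC2": noise})
        labels = np.array(["A"] * n + ["B"] * n)
        selected, relaxed = discriminating_pcs_ttest(scores, labels)
        assert selected == ["PC1"]
        assert not relaxed

    def test_identical_groups_return_empty_with_flag(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame({"PC1": rng.normal(size=20)})
        labels = np.array(["A"] * 10 + ["B"] * 10)
        selected, relaxed = discriminating_pcs_ttest(scores, labels)
        assert selected == []
        assert relaxed

    def test_two_stage_threshold_order(self):
        # separation large enough for the relaxed but not the strict cutoff
        rng = np.random.default_rng(4)
        n = 40
        sep = np.concatenate([rng.normal(0, 1, n), rng.normal(2.7, 1, n)])
        scores = pd.DataFrame({"PC1": sep})
        labels = np.array(["A"] * n + ["B"] * n)
        _, p = stats.ttest_ind(sep[:n], sep[n:], equal_var=True)
        selected, relaxed = discriminating_pcs_ttest(scores, labels)
        if 1e-20 <= p < 1e-15:
            assert selected == ["PC1"] and relaxed
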