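"""Imputation methods: exact-recovery limits, invariants, simulations."""

import numpy as np
import pytest

from gelimpute import (
    KnnConfig,
    LsimputeConfig,
    NipalsConfig,
    SyntheticConfig,
    ValidationError,
    average_variance,
    generate_complete_dataset,
    get_imputer,
    impute_em,
    impute_knn,
    impute_ls_array,
    impute_ls_combined,
    impute_ls_gene,
    impute_nipals,
    impute_row_average,
    normalized_rmse,
    remove_at_random,
)
from gelimpute.impute import _nipals_core

from conftest import make_matrix

ALL_LABELS = [
    "RowAve",
    "KNN(3)",
    "LSM.LS.G",
    "LSM.EM.G",
    "LSM.LS.A",
    "LSM.EM.A",
    "LSM.LS.C",
    "LSM.LS.Ad",
    "NIPALS(2)",
]


@pytest.fixture(scope="module")
def masked_pair():
    ds = generate_complete_dataset(SyntheticConfig(seed=77))
    masked, record = remove_at_random(ds.matrix, 0.2, seed=77)
    return ds.matrix, masked, record


class TestSharedInvariants:
    @pytest.mark.parametrize("label", ALL_LABELS)
    def test_identity_on_complete_matrix(self, label, default_matrix):
        res = get_imputer(label)(default_matrix)
        assert res.imputed_cells == []
        np.testing.assert_array_equal(res.matrix.values, default_matrix.values)

    @pytest.mark.parametrize("label", ALL_LABELS)
    def test_observed_cells_untouched(self, label, masked_pair):
        _, masked, _ = masked_pair
        res = get_imputer(label)(masked)
        obs = masked.observed()
        np.testing.assert_array_equal(res.matrix.values[obs], masked.values[obs])
        assert res.matrix.is_complete
        assert len(res.imputed_cells) == masked.n_missing

    @pytest.mark.parametrize("label", ALL_LABELS)
    def test_deterministic(self, label, masked_pair):
        _, masked, _ = masked_pair
        r1 = get_imputer(label)(masked)
        r2 = get_imputer(label)(masked)
        np.testing.assert_array_equal(r1.matrix.values, r2.matrix.values)

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            get_imputer("LSM.XX")


class TestRowAverage:
    def test_mean_of_observed(self):
        m = make_matrix([[2, 4, np.nan, 6], [1, 1, 1, 1]])
        res = impute_row_average(m)
        assert res.matrix.values[0, 2] == pytest.approx(4.0)

    def test_constant_row(self):
        m = make_matrix([[5, np.nan, 5, 5], [1, 2, 3, 4]])
        assert impute_row_average(m).matrix.values[0, 1] == pytest.approx(5.0)

    def test_all_missing_row_names_spot(self):
        m = make_matrix([[np.nan] * 4, [1, 2, 3, 4]])
        with pytest.raises(ValidationError, match="S001"):
            impute_row_average(m)

    def test_never_increases_average_variance(self, masked_pair):
        complete, masked, _ = masked_pair
        res = impute_row_average(masked)
        assert average_variance(res.matrix) <= average_variance(complete)


class TestKnn:
    def test_duplicate_row_recovered_exactly(self):
        m = make_matrix([[1, 2, 3, 4], [1, 2, 3, np.nan], [9, 1, 7, 2]])
        res = impute_knn(m, KnnConfig(k=1))
        assert res.matrix.values[1, 3] == pytest.approx(4.0)

    def test_uniform_all_neighbors_equals_column_mean(self):
        vals = np.array(
            [[1.0, 5.0, 2.0, 1.0], [2.0, 1.0, 8.0, 3.0], [4.0, 2.0, 3.0, 7.0],
             [3.0, 9.0, np.nan, 2.0]]
        )
        m = make_matrix(vals)
        res = impute_knn(m, KnnConfig(k=3, weighting="uniform"))
        assert res.matrix.values[3, 2] == pytest.approx(np.mean([2.0, 8.0, 3.0]))

    def test_zero_distance_short_circuit(self):
        # rows 0 and 1 coincide on observed gels; inverse-distance must
        # return the twin's value even with other close neighbors around
        m = make_matrix(
            [[1, 2, 3, 4], [1, 2, 3, np.nan], [1.01, 2.01, 3.01, 100.0]]
        )
        res = impute_knn(m, KnnConfig(k=2, weighting="inverse_distance"))
        assert res.matrix.values[1, 3] == pytest.approx(4.0)

    def test_k_must_be_below_n_spots(self, default_matrix):
        with pytest.raises(ValidationError):
            impute_knn(default_matrix, KnnConfig(k=70))

    def test_imputed_within_neighbor_range(self, masked_pair):
        _, masked, _ = masked_pair
        res = impute_knn(masked, KnnConfig(k=5))
        lo, hi = np.nanmin(masked.values), np.nanmax(masked.values)
        vals = np.array([v for _, _, v in res.imputed_cells])
        assert (vals >= lo).all() and (vals <= hi).all()


class TestLsGene:
    def test_perfectly_correlated_neighbor(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        vals = np.vstack([base, 2 * base, 1 + 0 * base])
        vals[1, 5] = np.nan
        m = make_matrix(vals, 3, 3)
        res = impute_ls_gene(m, LsimputeConfig(variant="LS.G"))
        assert res.matrix.values[1, 5] == pytest.approx(12.0, abs=1e-9)

    def test_single_candidate_equals_its_regression(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, 6)
        y = 3 * x + 1 + rng.normal(0, 0.1, 6)
        vals = np.vstack([x, y])
        vals[1, 0] = np.nan
        m = make_matrix(vals, 3, 3)
        res = impute_ls_gene(m)
        b = np.cov(x[1:], y[1:], ddof=1)[0, 1] / np.var(x[1:], ddof=1)
        a = y[1:].mean() - b * x[1:].mean()
        assert res.matrix.values[1, 0] == pytest.approx(a + b * x[0], rel=1e-9)

    def test_uncorrelated_neighbors_no_better_than_row_average(self):
        """With pure-noise neighbors the regressions cannot beat the row mean."""
        rng = np.random.default_rng(8)
        ls_err = ra_err = 0.0
        for rep in range(300):
            vals = rng.uniform(1, 10, size=(12, 6))
            truth = vals[0, 0]
            vals = vals.copy()
            vals[0, 0] = np.nan
            m = make_matrix(vals, 3, 3)
            ls_err += abs(impute_ls_gene(m).matrix.values[0, 0] - truth)
            ra_err += abs(impute_row_average(m).matrix.values[0, 0] - truth)
        assert ls_err >= 0.9 * ra_err


class TestLsArray:
    def test_linearly_dependent_gel_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 10, size=(8, 1))
        vals = base @ np.array([[1.0, 2.0, 1.5, 0.5]])
        vals[3, 1] = np.nan
        m = make_matrix(vals)
        res = impute_ls_array(m)
        assert res.matrix.values[3, 1] == pytest.approx(2 * base[3, 0], abs=1e-9)

    def test_transpose_symmetry_with_ls_gene(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 10, size=(10, 8))
        vals[2, 3] = np.nan
        vals[7, 0] = np.nan
        m = make_matrix(vals, 4, 4)
        mt = make_matrix(vals.T, 5, 5)
        a = impute_ls_array(m).matrix.values
        g = impute_ls_gene(mt).matrix.values
        np.testing.assert_allclose(a, g.T, rtol=1e-12)


class TestEm:
    def test_zero_iterations_equals_ls_init(self, masked_pair):
        _, masked, _ = masked_pair
        em0 = impute_em(masked, LsimputeConfig(variant="EM.A", em_max_iter=0))
        ls = impute_ls_array(masked, LsimputeConfig(variant="LS.A"))
        np.testing.assert_array_equal(em0.matrix.values, ls.matrix.values)

    def test_noiseless_gel_dependence_recovered(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 10, size=(10, 1))
        vals = base @ np.array([[1.0, 2.0, 0.5, 1.5]])
        truth = vals[4, 1]
        vals[4, 1] = np.nan
        res = impute_em(make_matrix(vals), LsimputeConfig(variant="EM.A"))
        assert res.matrix.values[4, 1] == pytest.approx(truth, rel=1e-3)

    def test_beats_row_average_under_gel_covariance(self):
        """Factor-structured gel covariance: EM.A < RowAve in NRMSE.

        Unequal factor loadings make equal-weight row averaging
        suboptimal, which is exactly the structure the conditional
        expectation exploits.
        """
        rng = np.random.default_rng(6)
        loadings = np.linspace(0.5, 3.0, 12)
        cov = np.outer(loadings, loadings) + 0.09 * np.eye(12)
        mean = np.full(12, 20.0)
        em_scores, ra_scores = [], []
        for rep in range(60):
            vals = rng.multivariate_normal(mean, cov, size=40)
            vals = np.abs(vals)
            m = make_matrix(vals, 6, 6)
            masked, record = remove_at_random(m, 0.2, seed=rep)
            em_scores.append(
                normalized_rmse(record, impute_em(masked, LsimputeConfig(variant="EM.A")))
            )
            ra_scores.append(normalized_rmse(record, impute_row_average(masked)))
        assert np.mean(em_scores) < np.mean(ra_scores)


class TestLsCombined:
    def test_endpoints_match_gene_and_array(self, masked_pair):
        _, masked, _ = masked_pair
        cfg = LsimputeConfig(variant="LS.C")
        gene = impute_ls_gene(masked, cfg).matrix.values
        arr = impute_ls_array(masked, cfg).matrix.values
        at_one = impute_ls_combined(masked, cfg, global_p=1.0).matrix.values
        at_zero = impute_ls_combined(masked, cfg, global_p=0.0).matrix.values
        np.testing.assert_allclose(at_one, gene, rtol=1e-12)
        np.testing.assert_allclose(at_zero, arr, rtol=1e-12)

    def test_adaptive_weights_lie_between_endpoints(self, masked_pair):
        _, masked, _ = masked_pair
        cfg = LsimputeConfig(variant="LS.Ad")
        gene = impute_ls_gene(masked).matrix.values
        arr = impute_ls_array(masked).matrix.values
        ad = impute_ls_combined(masked, cfg).matrix.values
        miss = np.isnan(masked.values)
        lo = np.minimum(gene[miss], arr[miss])
        hi = np.maximum(gene[miss], arr[miss])
        assert (ad[miss] >= lo - 1e-9).all() and (ad[miss] <= hi + 1e-9).all()

    def test_array_structure_drives_p_below_half(self):
        """Independent spots + correlated gels: the hold-out favors the array side."""
        rng = np.random.default_rng(9)
        cov = 0.9 * np.ones((12, 12)) + 0.1 * np.eye(12)
        below = 0
        n_rep = 50
        for rep in range(n_rep):
            vals = np.abs(rng.multivariate_normal(np.full(12, 20.0), cov, size=40))
            masked, _ = remove_at_random(make_matrix(vals, 6, 6), 0.2, seed=rep)
            res = impute_ls_combined(masked, LsimputeConfig(variant="LS.C", seed=rep))
            p = float(
                next(f for f in res.warning_flags if f.startswith("global_p=")).split("=")[1]
            )
            below += p < 0.5
        assert below >= 0.9 * n_rep


class TestNipals:
    def test_reconstruction_matches_svd_on_complete_data(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 8))
        Xc = X - X.mean(axis=1, keepdims=True)
        recon, converged = _nipals_core(Xc, 3, 1e-12, 5000)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        assert converged
        np.testing.assert_allclose(recon, (U[:, :3] * s[:3]) @ Vt[:3], atol=1e-8)

    def test_rank_one_completion_without_centering(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([2.0, 1.0, 4.0, 3.0])
        vals = np.outer(u, v)
        truth = vals[2, 1]
        vals[2, 1] = np.nan
        res = impute_nipals(make_matrix(vals), NipalsConfig(n_components=1, center=False))
        assert res.matrix.values[2, 1] == pytest.approx(truth, abs=1e-6)

    def test_centered_rank_one_completion(self):
        # loading zero at the masked column keeps the observed row mean exact
        t = np.array([1.0, -2.0, 3.0, 0.5, -1.5])
        p = np.array([1.0, -1.0, 2.0, -2.0, 0.0])
        mu = np.array([10.0, 12.0, 9.0, 11.0, 10.5])
        vals = mu[:, None] + np.outer(t, p)
        truth = vals[1, 4]
        vals[1, 4] = np.nan
        res = impute_nipals(make_matrix(vals, 3, 2), NipalsConfig(n_components=1))
        assert res.matrix.values[1, 4] == pytest.approx(truth, abs=1e-6)

    def test_nrmse_increases_with_missing_fraction(self, default_matrix):
        means = {}
        for frac in (0.05, 0.20):
            scores = []
            for rep in range(30):
                masked, record = remove_at_random(default_matrix, frac, seed=300 + rep)
                res = impute_nipals(masked, NipalsConfig(n_components=2))
                scores.append(normalized_rmse(record, res))
            means[frac] = np.mean(scores)
        assert means[0.05] < means[0.20]

    def test_component_cap(self, default_matrix):
        with pytest.raises(ValidationError):
            impute_nipals(default_matrix, NipalsConfig(n_components=13))
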