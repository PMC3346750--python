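"""Marginal likelihood, Woodbury terms, gradients and posterior."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from sparsegrn.model_core import (
    ExpressionDataset,
    ModelParameters,
    efficient_inverse_terms,
    marginal_covariance,
    negative_log_likelihood,
    nll_gradient,
    pack_gradient,
    pack_parameters,
    penalized_objective,
    penalty_mask,
    posterior_latent,
    unpack_parameters,
)
from conftest import make_dataset, make_params


class TestMarginalCovariance:
    def test_zero_loadings_give_scaled_identity(self):
        params = ModelParameters(
            W=np.zeros((2, 0)), Lambda=np.zeros((2, 1)), mu=np.zeros(2), sigma2=1.0
        )
        np.testing.assert_allclose(marginal_covariance(params), np.eye(2))

    def test_direct_arithmetic(self):
        params = ModelParameters(
            W=np.zeros((2, 0)), Lambda=[[1.0], [1.0]], mu=np.zeros(2), sigma2=0.5
        )
        np.testing.assert_allclose(
            marginal_covariance(params), [[1.5, 1.0], [1.0, 1.5]]
        )

    def test_smallest_eigenvalue_floor(self, rng):
        params = make_params(rng, p=6, d=0, q=2, sigma2=0.3)
        C = marginal_covariance(params)
        evals_C = np.linalg.eigvalsh(C)
        evals_LLt = np.linalg.eigvalsh(params.Lambda @ params.Lambda.T)
        assert evals_C[0] == pytest.approx(0.3 + evals_LLt[0], abs=1e-10)
        assert evals_C[0] >= 0.3 - 1e-12


class TestEfficientInverseTerms:
    def test_q_zero_diagonal_determinant(self):
        params = ModelParameters(
            W=np.zeros((3, 0)), Lambda=np.zeros((3, 0)), mu=np.zeros(3), sigma2=2.0
        )
        M, logdet = efficient_inverse_terms(params)
        assert M.shape == (0, 0)
        assert logdet == pytest.approx(3 * math.log(2.0))

    def test_two_by_two_determinant(self):
        params = ModelParameters(
            W=np.zeros((2, 0)), Lambda=[[1.0], [1.0]], mu=np.zeros(2), sigma2=0.5
        )
        M, logdet = efficient_inverse_terms(params)
        np.testing.assert_allclose(M, [[2.5]])
        assert logdet == pytest.approx(math.log(1.25))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_logdet(self, seed):
        rng = np.random.default_rng(seed)
        params = make_params(rng, p=10, d=0, q=3, sigma2=0.4)
        _, logdet = efficient_inverse_terms(params)
        sign, dense = np.linalg.slogdet(marginal_covariance(params))
        assert sign > 0
        assert logdet == pytest.approx(dense, abs=1e-8)


class TestNegativeLogLikelihood:
    def test_standard_normal_density(self):
        params = ModelParameters(
            W=np.zeros((1, 0)), Lambda=np.zeros((1, 0)), mu=[0.0], sigma2=1.0
        )
        data = ExpressionDataset(
            X=[[0.0], [0.0]], R=np.zeros((2, 0)),
            gene_ids=["g"], tf_ids=[], sample_ids=["a", "b"],
        )
        # two copies of x = 0 under N(0, 1)
        assert negative_log_likelihood(params, data) == pytest.approx(
            2 * 0.5 * math.log(2 * math.pi)
        )
        data1 = ExpressionDataset(
            X=[[1.0], [1.0]], R=np.zeros((2, 0)),
            gene_ids=["g"], tf_ids=[], sample_ids=["a", "b"],
        )
        assert negative_log_likelihood(params, data1) == pytest.approx(
            2 * (0.5 * math.log(2 * math.pi) + 0.5)
        )

    def test_matches_dense_multivariate_normal(self, rng):
        p, d, q, n = 8, 2, 2, 5
        params = make_params(rng, p, d, q)
        data = make_dataset(rng, n, p, d)
        C = marginal_covariance(params)
        dense = -sum(
            multivariate_normal.logpdf(
                data.X[i], mean=params.W @ data.R[i] + params.mu, cov=C
            )
            for i in range(n)
        )
        assert negative_log_likelihood(params, data) == pytest.approx(dense, abs=1e-8)

    def test_dimension_mismatch_names_axis(self, rng):
        params = make_params(rng, p=4, d=2, q=1)
        data = make_dataset(rng, n=5, p=4, d=3)
        with pytest.raises(ValueError, match="TF axis"):
            negative_log_likelihood(params, data)

    def test_invariant_to_sign_flip_and_column_permutation(self, rng):
        p, d, q, n = 7, 2, 3, 6
        params = make_params(rng, p, d, q)
        data = make_dataset(rng, n, p, d)
        base = negative_log_likelihood(params, data)
        flipped = ModelParameters(
            W=params.W, Lambda=params.Lambda * np.array([-1, 1, -1]),
            mu=params.mu, sigma2=params.sigma2,
        )
        permuted = ModelParameters(
            W=params.W, Lambda=params.Lambda[:, [2, 0, 1]],
            mu=params.mu, sigma2=params.sigma2,
        )
        assert negative_log_likelihood(flipped, data) == pytest.approx(base)
        assert negative_log_likelihood(permuted, data) == pytest.approx(base)


class TestGradient:
    def test_zero_at_ols_solution(self, rng):
        p, d, n = 4, 2, 30
        data = make_dataset(rng, n, p, d)
        Z = np.column_stack([np.ones(n), data.R])
        beta, *_ = np.linalg.lstsq(Z, data.X, rcond=None)
        resid = data.X - Z @ beta
        params = ModelParameters(
            W=beta[1:].T, Lambda=np.zeros((p, 0)), mu=beta[0],
            sigma2=float(np.mean(resid**2)),
        )
        grad = nll_gradient(params, data)
        np.testing.assert_allclose(grad.dW, 0, atol=1e-8)
        np.testing.assert_allclose(grad.dmu, 0, atol=1e-8)
        assert grad.dnu == pytest.approx(0, abs=1e-8)

    def test_zero_loadings_stationary_without_residual_structure(self):
        # Lambda = 0 is a stationary point of the loading gradient.
        p, n = 3, 10
        rng = np.random.default_rng(3)
        X = rng.standard_normal((n, p))
        data = ExpressionDataset(
            X=X, R=np.zeros((n, 0)), gene_ids=[f"g{i}" for i in range(p)],
            tf_ids=[], sample_ids=[f"s{i}" for i in range(n)],
        )
        params = ModelParameters(
            W=np.zeros((p, 0)), Lambda=np.zeros((p, 2)),
            mu=X.mean(0), sigma2=1.3,
        )
        grad = nll_gradient(params, data)
        np.testing.assert_allclose(grad.dLambda, 0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        p, d, q, n = 12, 3, 2, 20
        params = make_params(rng, p, d, q)
        data = make_dataset(rng, n, p, d)
        vec = pack_parameters(params)
        grad = pack_gradient(nll_gradient(params, data))

        def f(v):
            return negative_log_likelihood(unpack_parameters(v, p, d, q), data)

        h = 1e-5
        num = np.array(
            [
                (f(vec + h * e) - f(vec - h * e)) / (2 * h)
                for e in np.eye(vec.size)
            ]
        )
        rel = np.abs(grad - num) / np.maximum(np.abs(num), 1e-6)
        assert rel.max() < 1e-5


class TestPenalizedObjective:
    def test_zero_penalty_is_plain_nll(self, rng):
        params = make_params(rng, 5, 2, 1)
        data = make_dataset(rng, 6, 5, 2)
        assert penalized_objective(params, data, 0.0) == pytest.approx(
            negative_log_likelihood(params, data)
        )

    def test_l1_arithmetic(self):
        params = ModelParameters(
            W=[[2.0]], Lambda=[[-3.0]], mu=[0.0], sigma2=1.0
        )
        data = ExpressionDataset(
            X=[[0.1], [0.2]], R=[[0.3], [0.4]],
            gene_ids=["g"], tf_ids=["t"], sample_ids=["a", "b"],
        )
        nll = negative_log_likelihood(params, data)
        assert penalized_objective(params, data, 1.0) == pytest.approx(nll + 5.0)

    def test_monotone_in_penalty(self, rng):
        params = make_params(rng, 5, 2, 1)
        data = make_dataset(rng, 6, 5, 2)
        grid = np.linspace(0, 10, 11)
        vals = [penalized_objective(params, data, lam) for lam in grid]
        assert np.all(np.diff(vals) >= 0)

    def test_negative_penalty_rejected(self, rng):
        params = make_params(rng, 3, 1, 1)
        data = make_dataset(rng, 4, 3, 1)
        with pytest.raises(ValueError):
            penalized_objective(params, data, -0.1)


class TestPosteriorLatent:
    def test_zero_loadings_recover_prior(self):
        params = ModelParameters(
            W=np.zeros((3, 0)), Lambda=np.zeros((3, 2)), mu=np.zeros(3), sigma2=1.0
        )
        mean, cov = posterior_latent(params, np.zeros(0), np.ones(3))
        np.testing.assert_allclose(mean, 0)
        np.testing.assert_allclose(cov, np.eye(2))

    def test_large_noise_shrinks_to_prior_mean(self, rng):
        params = make_params(rng, p=5, d=0, q=2, sigma2=1e8)
        mean, _ = posterior_latent(params, np.zeros(0), rng.standard_normal(5))
        np.testing.assert_allclose(mean, 0, atol=1e-6)

    def test_matches_dense_bayes_formula(self, rng):
        p, d, q = 6, 2, 2
        params = make_params(rng, p, d, q, sigma2=0.5)
        r = rng.standard_normal(d)
        x = rng.standard_normal(p)
        mean, cov = posterior_latent(params, r, x)
        C = marginal_covariance(params)
        delta = x - params.W @ r - params.mu
        dense_mean = params.Lambda.T @ np.linalg.solve(C, delta)
        dense_cov = np.eye(q) - params.Lambda.T @ np.linalg.solve(C, params.Lambda)
        np.testing.assert_allclose(mean, dense_mean, atol=1e-8)
        np.testing.assert_allclose(cov, dense_cov, atol=1e-8)


class TestFlattening:
    def test_roundtrip_and_mask_blocks(self, rng):
        p, d, q = 4, 2, 3
        params = make_params(rng, p, d, q, sigma2=0.9)
        vec = pack_parameters(params)
        back = unpack_parameters(vec, p, d, q)
        np.testing.assert_allclose(back.W, params.W)
        np.testing.assert_allclose(back.Lambda, params.Lambda)
        np.testing.assert_allclose(back.mu, params.mu)
        assert back.sigma2 == pytest.approx(params.sigma2)
        mask = penalty_mask(p, d, q)
        assert mask.sum() == p * (d + q)
        assert not mask[-(p + 1):].any()


class TestDatasetInvariants:
    def test_overlapping_identifiers_rejected(self, rng):
        with pytest.raises(ValueError, match="overlap"):
            ExpressionDataset(
                X=rng.standard_normal((3, 2)), R=rng.standard_normal((3, 1)),
                gene_ids=["a", "b"], tf_ids=["a"], sample_ids=["s1", "s2", "s3"],
            )

    def test_non_finite_rejected(self, rng):
        X = rng.standard_normal((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputation"):
            ExpressionDataset(
                X=X, R=np.zeros((3, 0)), gene_ids=["a", "b"], tf_ids=[],
                sample_ids=["s1", "s2", "s3"],
            )
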