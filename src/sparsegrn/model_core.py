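"""Two-layer linear-Gaussian model of transcriptional regulation.

Gene expression ``x`` (p genes) is modeled as a linear function of observed
transcription-factor expression ``r`` (d TFs) plus ``q`` hidden Gaussian
factors ``z`` and isotropic Gaussian noise::

    x = W r + Lambda z + mu + eps,   z ~ N(0, I_q),  eps ~ N(0, sigma2 I_p)

Integrating out ``z`` gives a Gaussian marginal with mean ``W r + mu`` and
low-rank-plus-diagonal covariance ``C = Lambda Lambda^T + sigma2 I``, so all
likelihood computations use the Woodbury identity through the q x q matrix
``M = sigma2 I_q + Lambda^T Lambda`` and never invert a p x p matrix.

Both limits of the model are legal: ``q = 0`` is per-gene linear regression
on TFs, ``d = 0`` is probabilistic PCA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ExpressionDataset",
    "ModelParameters",
    "ModelGradient",
    "FitConfig",
    "marginal_covariance",
    "efficient_inverse_terms",
    "negative_log_likelihood",
    "nll_gradient",
    "penalized_objective",
    "posterior_latent",
    "pack_parameters",
    "pack_gradient",
    "unpack_parameters",
    "penalty_mask",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class ExpressionDataset:
    """Samples-by-genes matrix ``X`` paired with a samples-by-TFs matrix ``R``.

    Gene and TF identifier sets are disjoint: the regulated (lower-layer)
    genes exclude the TFs themselves, which keeps the implied graph bipartite
    and acyclic. All entries must be finite — impute before constructing.
    """

    X: np.ndarray
    R: np.ndarray
    gene_ids: list[str]
    tf_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x genes)")
        if self.R.ndim != 2:
            raise ValueError("R must be 2-D (samples x TFs)")
        n, p = self.X.shape
        if self.R.shape[0] != n:
            raise ValueError(
                f"sample axis mismatch: X has {n} rows, R has {self.R.shape[0]}"
            )
        if n < 2:
            raise ValueError("need at least 2 samples")
        if p < 1:
            raise ValueError("need at least 1 gene")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match X columns")
        if len(self.tf_ids) != self.R.shape[1]:
            raise ValueError("tf_ids length does not match R columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match rows")
        overlap = set(self.gene_ids) & set(self.tf_ids)
        if overlap:
            raise ValueError(f"gene and TF identifiers overlap: {sorted(overlap)[:5]}")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.R)):
            raise ValueError("non-finite entries; run imputation before modeling")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def n_tfs(self) -> int:
        return self.R.shape[1]

    def subset(self, indices) -> "ExpressionDataset":
        """New dataset restricted to the given sample indices."""
        idx = np.asarray(indices)
        return ExpressionDataset(
            X=self.X[idx],
            R=self.R[idx],
            gene_ids=list(self.gene_ids),
            tf_ids=list(self.tf_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class ModelParameters:
    """Fitted parameters: TF weights W (p x d), loadings Lambda (p x q),
    intercept mu (p,) and isotropic noise variance sigma2 > 0.

    The latent factors themselves are never stored; they are integrated out
    of the likelihood. Sign/column-permutation of ``Lambda`` is not
    identifiable and consumers must match columns accordingly.
    """

    W: np.ndarray
    Lambda: np.ndarray
    mu: np.ndarray
    sigma2: float
    gene_ids: list[str] | None = None
    tf_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        p = self.mu.shape[0]
        if self.W.size == 0:
            self.W = self.W.reshape(p, 0)
        if self.Lambda.size == 0:
            self.Lambda = self.Lambda.reshape(p, 0)
        if self.W.shape[0] != p:
            raise ValueError(f"W has {self.W.shape[0]} rows, mu has {p} entries")
        if self.Lambda.shape[0] != p:
            raise ValueError(f"Lambda has {self.Lambda.shape[0]} rows, mu has {p}")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    @property
    def q(self) -> int:
        return self.Lambda.shape[1]


@dataclass
class ModelGradient:
    """Gradient of the NLL in the same block structure as ModelParameters.

    ``dnu`` is the derivative with respect to nu = log(sigma2): the noise is
    optimized on the log scale so the domain stays unconstrained.
    """

    dW: np.ndarray
    dLambda: np.ndarray
    dmu: np.ndarray
    dnu: float


@dataclass
class FitConfig:
    """Optimization settings for penalized maximum marginal likelihood.

    penalty is the L1 weight on W and Lambda (mu and sigma2 are never
    penalized); q the number of hidden factors; tol the convergence tolerance
    applied both to the relative objective decrease (over 5 consecutive
    iterations) and the pseudo-gradient infinity norm.
    """

    penalty: float = 0.0
    q: int = 0
    max_iter: int = 500
    tol: float = 1e-9
    lbfgs_memory: int = 10
    n_restarts: int = 10
    seed: int = 0
    center: bool = True
    scale: bool = False

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.q < 0:
            raise ValueError("q must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.lbfgs_memory < 1:
            raise ValueError("lbfgs_memory must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


def _check_dims(params: ModelParameters, data: ExpressionDataset) -> None:
    if params.p != data.n_genes:
        raise ValueError(
            f"gene axis mismatch: model has p={params.p}, data has {data.n_genes}"
        )
    if params.d != data.n_tfs:
        raise ValueError(
            f"TF axis mismatch: model has d={params.d}, data has {data.n_tfs}"
        )


def marginal_covariance(params: ModelParameters) -> np.ndarray:
    """Dense marginal covariance C = Lambda Lambda^T + sigma2 I (p x p).

    For diagnostics and small problems only; likelihood code goes through
    :func:`efficient_inverse_terms` instead.
    """
    p = params.p
    return params.Lambda @ params.Lambda.T + params.sigma2 * np.eye(p)


def efficient_inverse_terms(params: ModelParameters) -> tuple[np.ndarray, float]:
    """Return (M, log|C|) with M = sigma2 I_q + Lambda^T Lambda.

    By the Woodbury identity C^{-1} = (I - Lambda M^{-1} Lambda^T) / sigma2
    and the determinant lemma log|C| = (p - q) log sigma2 + log|M|, so
    quadratic forms and the log-determinant cost O(p q^2) instead of O(p^3).
    """
    p, q = params.p, params.q
    log_s2 = math.log(params.sigma2)
    if q == 0:
        return np.empty((0, 0)), p * log_s2
    M = params.sigma2 * np.eye(q) + params.Lambda.T @ params.Lambda
    sign, logdet_M = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet_M):
        raise np.linalg.LinAlgError(
            "M = sigma2 I + Lambda'Lambda is numerically singular; "
            "Lambda likely contains overflow or NaN"
        )
    return M, (p - q) * log_s2 + logdet_M


def _residuals(params: ModelParameters, data: ExpressionDataset) -> np.ndarray:
    """N x p residual matrix Delta with rows x_n - W r_n - mu."""
    Delta = data.X - params.mu
    if params.d > 0:
        Delta = Delta - data.R @ params.W.T
    return Delta


def negative_log_likelihood(params: ModelParameters, data: ExpressionDataset) -> float:
    """Negative log marginal likelihood of X given R, latent factors integrated out.

    sum_n [ p/2 log 2pi + 1/2 log|C| + 1/2 (x_n - W r_n - mu)' C^{-1} (...) ]
    """
    _check_dims(params, data)
    n, p = data.n_samples, data.n_genes
    M, log_det_C = efficient_inverse_terms(params)
    Delta = _residuals(params, data)
    total_sq = float(np.sum(Delta * Delta))
    if params.q > 0:
        T = Delta @ params.Lambda  # N x q
        cho = cho_factor(M, lower=True)
        total_sq -= float(np.sum(T * cho_solve(cho, T.T).T))
    quad = total_sq / params.sigma2
    return 0.5 * (n * p * LOG_2PI + n * log_det_C + quad)


def nll_gradient(params: ModelParameters, data: ExpressionDataset) -> ModelGradient:
    """Analytic gradient of the NLL w.r.t. W, Lambda, mu and nu = log sigma2.

    With S = sum_n delta_n delta_n' (never materialized):

        dNLL/dW      = -C^{-1} Delta' R
        dNLL/dmu     = -C^{-1} sum_n delta_n
        dNLL/dLambda =  N C^{-1} Lambda - C^{-1} S C^{-1} Lambda
        dNLL/dsigma2 =  N/2 tr(C^{-1}) - 1/2 sum_n ||C^{-1} delta_n||^2

    All products are arranged as O(N p (d+q)) matrix multiplications through
    the Woodbury form of C^{-1}.
    """
    _check_dims(params, data)
    n, p, q = data.n_samples, data.n_genes, params.q
    s2 = params.sigma2
    Delta = _residuals(params, data)

    if q > 0:
        M = s2 * np.eye(q) + params.Lambda.T @ params.Lambda
        cho = cho_factor(M, lower=True)
        # Delta C^{-1} = (Delta - (Delta Lambda) M^{-1} Lambda') / sigma2
        T = Delta @ params.Lambda
        U = (Delta - cho_solve(cho, T.T).T @ params.Lambda.T) / s2
        CiL = cho_solve(cho, params.Lambda.T).T  # C^{-1} Lambda = Lambda M^{-1}
        dLambda = n * CiL - U.T @ (Delta @ CiL)
        Minv = cho_solve(cho, np.eye(q))
        tr_Cinv = (p - q) / s2 + float(np.trace(Minv))
    else:
        U = Delta / s2
        dLambda = np.zeros((p, 0))
        tr_Cinv = p / s2

    dmu = -U.sum(axis=0)
    dW = -(U.T @ data.R) if params.d > 0 else np.zeros((p, 0))
    dsigma2 = 0.5 * n * tr_Cinv - 0.5 * float(np.sum(U * U))
    return ModelGradient(dW=dW, dLambda=dLambda, dmu=dmu, dnu=s2 * dsigma2)


def penalized_objective(
    params: ModelParameters, data: ExpressionDataset, penalty: float
) -> float:
    """NLL plus penalty * (sum|W_ij| + sum|Lambda_ik|).

    Only the regulation weights and loadings are penalized — sparsity encodes
    non-regulation; the intercept and noise variance carry no such meaning.
    """
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    l1 = float(np.abs(params.W).sum() + np.abs(params.Lambda).sum())
    return negative_log_likelihood(params, data) + penalty * l1


def posterior_latent(
    params: ModelParameters, r: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior of the hidden factors for one sample.

    mean = M^{-1} Lambda' (x - W r - mu), covariance = sigma2 M^{-1}; with
    zero loadings the prior N(0, I) is recovered.
    """
    q = params.q
    if q == 0:
        return np.zeros(0), np.zeros((0, 0))
    x = np.asarray(x, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    if x.shape[0] != params.p:
        raise ValueError(f"x has {x.shape[0]} entries, model has p={params.p}")
    if r.shape[0] != params.d:
        raise ValueError(f"r has {r.shape[0]} entries, model has d={params.d}")
    delta = x - params.mu
    if params.d > 0:
        delta = delta - params.W @ r
    M = params.sigma2 * np.eye(q) + params.Lambda.T @ params.Lambda
    cho = cho_factor(M, lower=True)
    mean = cho_solve(cho, params.Lambda.T @ delta)
    cov = params.sigma2 * cho_solve(cho, np.eye(q))
    return mean, cov


# ---------------------------------------------------------------------------
# Flattening convention (frozen): [W row-major, Lambda row-major, mu, nu]
# with nu = log sigma2 as the final scalar. The L1 penalty mask marks the
# W and Lambda blocks only.
# ---------------------------------------------------------------------------


def pack_parameters(params: ModelParameters) -> np.ndarray:
    return np.concatenate(
        [
            params.W.ravel(),
            params.Lambda.ravel(),
            params.mu,
            [math.log(params.sigma2)],
        ]
    )


def unpack_parameters(
    vec: np.ndarray,
    p: int,
    d: int,
    q: int,
    gene_ids: list[str] | None = None,
    tf_ids: list[str] | None = None,
) -> ModelParameters:
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] != p * d + p * q + p + 1:
        raise ValueError("flat vector length inconsistent with (p, d, q)")
    W = vec[: p * d].reshape(p, d)
    Lam = vec[p * d : p * d + p * q].reshape(p, q)
    mu = vec[p * d + p * q : p * d + p * q + p]
    sigma2 = math.exp(vec[-1])
    return ModelParameters(
        W=W, Lambda=Lam, mu=mu, sigma2=sigma2, gene_ids=gene_ids, tf_ids=tf_ids
    )


def pack_gradient(grad: ModelGradient) -> np.ndarray:
    return np.concatenate(
        [grad.dW.ravel(), grad.dLambda.ravel(), grad.dmu, [grad.dnu]]
    )


def penalty_mask(p: int, d: int, q: int) -> np.ndarray:
    """Boolean mask over the flat vector: True on the W and Lambda blocks."""
    mask = np.zeros(p * d + p * q + p + 1, dtype=bool)
    mask[: p * (d + q)] = True
    return mask
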