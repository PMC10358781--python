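"""Factor analysis: static shared-variability model used to initialize the LDS
and as a no-dynamics baseline.

Backed by scikit-learn's EM FactorAnalysis; this wrapper adapts it to the
trial-structured data layout and parameter conventions used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FactorAnalysis

from .base import FitReport, as_trials_array, floor_variances

__all__ = ["FAParams", "fa_fit", "fa_posterior_mean"]


@dataclass
class FAParams:
    A: np.ndarray        # (q, p) loading
    b: np.ndarray        # (q,) mean
    R_diag: np.ndarray   # (q,) independent noise variances

    @property
    def q(self) -> int:
        return self.A.shape[0]

    @property
    def p(self) -> int:
        return self.A.shape[1]


def fa_fit(data, p: int, max_iter: int = 1000, tol: float = 1e-6,
           seed: int = 0) -> FitReport:
    """Maximum-likelihood FA (y = A z + b + eps, z ~ N(0, I), eps ~ N(0, diag R))."""
    Y = as_trials_array(data)
    n_trials, q, T = Y.shape
    if not (1 <= p < q):
        raise ValueError(f"need 1 <= p < q (got p={p}, q={q})")
    X = Y.transpose(0, 2, 1).reshape(n_trials * T, q)
    fa = FactorAnalysis(n_components=p, max_iter=max_iter, tol=tol,
                        random_state=seed, svd_method="lapack")
    fa.fit(X)
    params = FAParams(A=fa.components_.T.copy(), b=fa.mean_.copy(),
                      R_diag=floor_variances(fa.noise_variance_))
    ll = np.asarray(fa.loglike_) * X.shape[0]  # sklearn stores per-sample average
    return FitReport(params=params, loglik_trace=ll, n_iter=fa.n_iter_,
                     converged=fa.n_iter_ < max_iter, seed=seed, model_id="fa")


def fa_posterior_mean(params: FAParams, Y) -> np.ndarray:
    """E[z_t | y_t] per time point: Aᵀ(A Aᵀ + R)⁻¹ (y_t - b). Returns (trials, p, T)."""
    Y = as_trials_array(Y)
    A, R = params.A, params.R_diag
    Sigma = A @ A.T + np.diag(R)
    W = np.linalg.solve(Sigma, A).T          # (p, q)
    return np.einsum("pq,bqt->bpt", W, Y - params.b[None, :, None])
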