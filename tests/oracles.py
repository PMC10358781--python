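"""Independent reference computations used by the tests.

These build the quantities being checked from first principles (explicit joint
Gaussians, exhaustive active-set enumeration, direct formulas) without using
the recursive implementations under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def joint_gaussian_smoother(model, Yt: np.ndarray):
    """Posterior moments and log likelihood of a linear-Gaussian state-space
    model by explicit construction of the joint covariance of all states and
    observations, followed by Schur-complement conditioning.

    Yt : (q, T) single-trial observations.
    Returns (post_mean (T, n) rows, post_cov (nT, nT), loglik).
    """
    n, q = model.n, model.q
    T = Yt.shape[-1]
    mean_x = np.zeros(n * T)
    mean_x[:n] = model.m0
    cov = np.zeros((n * T, n * T))
    cov[:n, :n] = model.S0
    for t in range(1, T):
        F, d, N = model.step_params(t)
        mean_x[t * n:(t + 1) * n] = F @ mean_x[(t - 1) * n:t * n] + d
        for s in range(t):
            blk = F @ cov[(t - 1) * n:t * n, s * n:(s + 1) * n]
            cov[t * n:(t + 1) * n, s * n:(s + 1) * n] = blk
            cov[s * n:(s + 1) * n, t * n:(t + 1) * n] = blk.T
        cov[t * n:(t + 1) * n, t * n:(t + 1) * n] = \
            F @ cov[(t - 1) * n:t * n, (t - 1) * n:t * n] @ F.T + N
    Hbig = np.kron(np.eye(T), model.H)
    mean_y = Hbig @ mean_x + np.tile(model.o, T)
    cov_y = Hbig @ cov @ Hbig.T + np.kron(np.eye(T), np.diag(model.r))
    yv = Yt.T.reshape(-1)
    sol = np.linalg.solve(cov_y, yv - mean_y)
    post_mean = mean_x + cov @ Hbig.T @ sol
    post_cov = cov - cov @ Hbig.T @ np.linalg.solve(cov_y, Hbig @ cov)
    _, logdet = np.linalg.slogdet(cov_y)
    ll = -0.5 * (len(yv) * np.log(2 * np.pi) + logdet
                 + (yv - mean_y) @ sol)
    return post_mean.reshape(T, n), post_cov, ll


def ar1_deconv_qp(y: np.ndarray, gamma: float, lam: float) -> tuple[np.ndarray, float]:
    """Exact minimizer of 1/2||y - c||^2 + lam * sum(s) s.t. s >= 0 (with
    s_1 = c_1) by exhaustive enumeration of active sets (small T only).

    The constraints are (Mc)_t >= 0 with M lower-bidiagonal; for each subset A
    the equality-constrained stationary point is solved and feasibility
    checked; the feasible point with the lowest objective is exact.
    """
    T = len(y)
    M = np.eye(T)
    for t in range(1, T):
        M[t, t - 1] = -gamma
    # objective: 1/2||y - c||^2 + lam * 1' M c
    grad_lin = lam * (M.T @ np.ones(T)) - y  # from 1/2 c'c - y'c + lin
    best_obj, best_c = np.inf, None
    for r in range(T + 1):
        for A in itertools.combinations(range(T), r):
            A = list(A)
            # minimize 1/2 c'c + grad_lin' c  s.t. (Mc)_A = 0
            if A:
                MA = M[A]
                KKT = np.block([[np.eye(T), MA.T], [MA, np.zeros((r, r))]])
                rhs = np.concatenate([-grad_lin, np.zeros(r)])
                try:
                    sol = np.linalg.solve(KKT, rhs)
                except np.linalg.LinAlgError:
                    continue
                c = sol[:T]
            else:
                c = -grad_lin
            if np.all(M @ c >= -1e-9):
                obj = 0.5 * np.sum((y - c) ** 2) + lam * np.sum(M @ c)
                if obj < best_obj - 1e-15:
                    best_obj, best_c = obj, c
    return best_c, best_obj


def pearson_by_hand(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / np.sqrt(np.sum(am ** 2) * np.sum(bm ** 2)))
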