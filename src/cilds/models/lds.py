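"""Latent linear dynamical system (LDS) on fluorescence or spike estimates.

    y_t = A z_t + b + eps_t,   eps_t ~ N(0, R)            (R diagonal)
    z_t = D z_{t-1} + v_t,     v_t  ~ N(0, P)             (D, P diagonal)
    z_1 ~ N(h1, G1)                                       (G1 diagonal)

Fitting is by EM with closed-form M-steps under the diagonality constraints.
A and b are initialized by factor analysis; D starts at 0.999 I (a stable
system) and P at the matching stationary-unit-variance level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..kalman import StateSpace, kalman_smooth, SmootherResult
from .base import FitReport, as_trials_array, floor_variances
from .fa import fa_fit

__all__ = ["LDSParams", "lds_smooth", "lds_em", "sample_lds"]


@dataclass
class LDSParams:
    A: np.ndarray        # (q, p) loading
    b: np.ndarray        # (q,) offset
    R_diag: np.ndarray   # (q,) observation noise variances
    D_diag: np.ndarray   # (p,) latent dynamics
    P_diag: np.ndarray   # (p,) latent noise variances
    h1: np.ndarray       # (p,) initial mean
    G1_diag: np.ndarray  # (p,) initial variances

    def __post_init__(self):
        q, p = np.shape(self.A)
        for name in ("b", "R_diag"):
            if len(getattr(self, name)) != q:
                raise ValueError(f"{name} must have length q={q}")
        for name in ("D_diag", "P_diag", "h1", "G1_diag"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} must have length p={p}")
        if np.any(self.R_diag <= 0) or np.any(self.P_diag <= 0) or np.any(self.G1_diag <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def q(self) -> int:
        return self.A.shape[0]

    @property
    def p(self) -> int:
        return self.A.shape[1]

    def to_state_space(self) -> StateSpace:
        p = self.p
        return StateSpace(F=np.diag(self.D_diag), d=np.zeros(p), N=np.diag(self.P_diag),
                          H=self.A, o=self.b, r=self.R_diag,
                          m0=self.h1, S0=np.diag(self.G1_diag))


def lds_smooth(params: LDSParams, Y) -> SmootherResult:
    """Exact posterior over z_{1..T} and exact log likelihood (Kalman/RTS)."""
    return kalman_smooth(params.to_state_space(), as_trials_array(Y))


def _init_from_fa(Y: np.ndarray, p: int, seed: int, fa_iters: int = 1000) -> LDSParams:
    fa = fa_fit(Y, p, max_iter=fa_iters, seed=seed)
    d0 = 0.999
    return LDSParams(A=fa.params.A, b=fa.params.b,
                     R_diag=floor_variances(fa.params.R_diag),
                     D_diag=np.full(p, d0), P_diag=np.full(p, 1.0 - d0 ** 2),
                     h1=np.zeros(p), G1_diag=np.ones(p))


def _em_stats(Y: np.ndarray, sm: SmootherResult):
    """Sufficient statistics summed over trials and time."""
    M = sm.means                      # (B, p, T)
    B, p, T = M.shape
    covs, lag = sm.covs, sm.lag_covs
    Szz_all = B * covs.sum(axis=0) + np.einsum("bit,bjt->ij", M, M)
    Sz_all = M.sum(axis=(0, 2))
    Sz1z1 = B * covs[:-1].sum(axis=0) + np.einsum("bit,bjt->ij", M[..., :-1], M[..., :-1])
    Szz2 = Szz_all - (B * covs[0] + np.einsum("bi,bj->ij", M[..., 0], M[..., 0]))
    Scross = B * lag.sum(axis=0) + np.einsum("bit,bjt->ij", M[..., 1:], M[..., :-1])
    Sy = Y.sum(axis=(0, 2))
    Syy = np.einsum("bqt,bqt->q", Y, Y)
    Syz = np.einsum("bqt,bpt->qp", Y, M)
    return dict(Szz_all=Szz_all, Sz_all=Sz_all, Sz1z1=Sz1z1, Szz2=Szz2,
                Scross=Scross, Sy=Sy, Syy=Syy, Syz=Syz, B=B, T=T)


def _m_step(params: LDSParams, st: dict) -> LDSParams:
    p, q = params.p, params.q
    B, T = st["B"], st["T"]
    NT = B * T

    # observation: joint least squares for [A, b] per neuron on expected moments
    G = np.empty((p + 1, p + 1))
    G[:p, :p] = st["Szz_all"]
    G[:p, p] = st["Sz_all"]
    G[p, :p] = st["Sz_all"]
    G[p, p] = NT
    RHS = np.hstack([st["Syz"], st["Sy"][:, None]])       # (q, p+1)
    coef = np.linalg.solve(G, RHS.T).T                    # (q, p+1)
    A = coef[:, :p]
    b = coef[:, p]
    quad = np.einsum("qi,ij,qj->q", coef, G, coef)
    R = floor_variances((st["Syy"] - 2.0 * np.sum(coef * RHS, axis=1) + quad) / NT)

    # diagonal latent dynamics, per coordinate
    cross_d = np.diag(st["Scross"])
    prev_d = np.diag(st["Sz1z1"])
    cur_d = np.diag(st["Szz2"])
    D = cross_d / prev_d
    P = floor_variances((cur_d - 2.0 * D * cross_d + D ** 2 * prev_d) / (B * (T - 1)))
    return replace(params, A=A, b=b, R_diag=R, D_diag=D, P_diag=P)


def _init_update(params: LDSParams, sm: SmootherResult) -> LDSParams:
    m1 = sm.means[:, :, 0]
    h1 = m1.mean(axis=0)
    G1 = floor_variances(np.diag(sm.covs[0]) + ((m1 - h1) ** 2).mean(axis=0))
    return replace(params, h1=h1, G1_diag=G1)


def lds_em(data, p: int, max_iter: int = 1500, tol: float = 1e-6,
           init: LDSParams | None = None, seed: int = 0,
           fa_iters: int = 1000) -> FitReport:
    """Fit the LDS by EM.

    Stops when the log-likelihood increase drops below `tol` or after
    `max_iter` iterations, whichever comes first.
    """
    Y = as_trials_array(data)
    _, q, T = Y.shape
    if not (1 <= p < q):
        raise ValueError(f"need 1 <= p < q (got p={p}, q={q})")
    params = init if init is not None else _init_from_fa(Y, p, seed, fa_iters)

    ll_trace = []
    converged = False
    for it in range(max_iter):
        sm = lds_smooth(params, Y)
        ll = sm.total_loglik
        ll_trace.append(ll)
        if len(ll_trace) > 1 and ll - ll_trace[-2] < tol:
            converged = True
            break
        st = _em_stats(Y, sm)
        params = _m_step(params, st)
        params = _init_update(params, sm)
    return FitReport(params=params, loglik_trace=np.asarray(ll_trace),
                     n_iter=len(ll_trace), converged=converged, seed=seed,
                     model_id="lds")


def sample_lds(params: LDSParams, T: int, n_trials: int, seed: int = 0):
    """Draw (Z, Y) from the generative LDS: Z (trials, p, T), Y (trials, q, T)."""
    from ..kalman import sample_state_space

    rng = np.random.default_rng(seed)
    X, Y = sample_state_space(params.to_state_space(), T, n_trials, rng)
    return X, Y
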