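"""CILDS and CIFA: joint deconvolution and dimensionality reduction.

CILDS replaces the spike input of the per-neuron AR(1) calcium model with a
shared latent drive, so deconvolution and latent inference are performed
jointly:

    y_t = B c_t + eps_t,                 eps_t ~ N(0, R)       t = 1..T
    c_t = Gamma c_{t-1} + A z_t + b + w_t,  w_t ~ N(0, Q)      t = 2..T
    c_1 ~ N(mu1, V1)
    z_t = D z_{t-1} + v_t,               v_t ~ N(0, P)         t = 3..T
    z_2 ~ N(h2, G2)

(B, R, Gamma, Q, V1, D, P, G2 diagonal; the first latent is z_2 since c_2 is
the first calcium state that receives a latent drive.)

CIFA is the same model with the latent dynamics removed: z_t ~ N(0, I)
independently for t = 2..T.

Inference and likelihoods are exact: the model is a standard linear-Gaussian
chain over the augmented state x_t = [c_t; z_t].  Because c_t depends on the
*current* z_t, substituting z_t = D z_{t-1} + v_t yields the stationary
transition [[Gamma, A D], [0, D]] with correlated process noise
[[A P Aᵀ + Q, A P], [P Aᵀ, P]].  The first state is x_1 = [c_1; z_2] and the
first transition carries z_2 through deterministically
(F1 = [[Gamma, A], [0, I]], noise [[Q, 0], [0, 0]]), which keeps y_1 in the
likelihood of the same single chain.  EM then reuses the generic smoother,
with closed-form M-steps under the diagonality constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..kalman import StateSpace, kalman_smooth, SmootherResult, sample_state_space
from .base import FitReport, as_trials_array, floor_variances

__all__ = ["CILDSParams", "CIFAParams", "cilds_smooth", "cilds_em", "cifa_fit",
           "sample_cilds"]

_GAMMA_EPS = 1e-6


@dataclass
class CILDSParams:
    B_diag: np.ndarray       # (q,) fluorescence gain
    R_diag: np.ndarray       # (q,) fluorescence noise variances
    Gamma_diag: np.ndarray   # (q,) per-frame calcium decay, in (0, 1)
    A: np.ndarray            # (q, p) latent-to-calcium loading
    b: np.ndarray            # (q,) calcium drive offset
    Q_diag: np.ndarray       # (q,) spiking-variability variances
    mu1: np.ndarray          # (q,) initial calcium mean
    V1_diag: np.ndarray      # (q,) initial calcium variances
    D_diag: np.ndarray       # (p,) latent dynamics
    P_diag: np.ndarray       # (p,) latent noise variances
    h2: np.ndarray           # (p,) initial latent mean
    G2_diag: np.ndarray      # (p,) initial latent variances

    def __post_init__(self):
        q, p = np.shape(self.A)
        # Gamma = 0 is admitted for the algebraic collapse onto LDS/FA
        if np.any(self.Gamma_diag < 0) or np.any(self.Gamma_diag >= 1):
            raise ValueError("calcium decay Gamma must lie in [0, 1)")
        if np.any(self.B_diag <= 0):
            raise ValueError("fluorescence gain B must be positive")
        for name in ("R_diag", "Q_diag", "V1_diag"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if len(getattr(self, name)) != q:
                raise ValueError(f"{name} must have length q={q}")
        for name in ("P_diag", "G2_diag"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")

    @property
    def q(self) -> int:
        return self.A.shape[0]

    @property
    def p(self) -> int:
        return self.A.shape[1]

    def to_state_space(self) -> StateSpace:
        q, p = self.q, self.p
        n = q + p
        A, D, P = self.A, self.D_diag, self.P_diag
        AD = A * D[None, :]
        AP = A * P[None, :]

        F = np.zeros((n, n))
        F[:q, :q] = np.diag(self.Gamma_diag)
        F[:q, q:] = AD
        F[q:, q:] = np.diag(D)
        N = np.zeros((n, n))
        N[:q, :q] = AP @ A.T + np.diag(self.Q_diag)
        N[:q, q:] = AP
        N[q:, :q] = AP.T
        N[q:, q:] = np.diag(P)
        d = np.concatenate([self.b, np.zeros(p)])

        F1 = np.zeros((n, n))
        F1[:q, :q] = np.diag(self.Gamma_diag)
        F1[:q, q:] = A
        F1[q:, q:] = np.eye(p)
        N1 = np.zeros((n, n))
        N1[:q, :q] = np.diag(self.Q_diag)

        H = np.zeros((q, n))
        H[:, :q] = np.diag(self.B_diag)
        m0 = np.concatenate([self.mu1, self.h2])
        S0 = np.zeros((n, n))
        S0[:q, :q] = np.diag(self.V1_diag)
        S0[q:, q:] = np.diag(self.G2_diag)
        return StateSpace(F=F, d=d, N=N, H=H, o=np.zeros(q), r=self.R_diag,
                          m0=m0, S0=S0, F1=F1, d1=d, N1=N1)


@dataclass
class CIFAParams(CILDSParams):
    """CILDS without latent dynamics: z_t ~ N(0, I) independently, t = 2..T.

    Realized as fixed D = 0, P = I, h2 = 0, G2 = I (never updated by EM)."""

    D_diag: np.ndarray | None = None
    P_diag: np.ndarray | None = None
    h2: np.ndarray | None = None
    G2_diag: np.ndarray | None = None

    def __post_init__(self):
        p = np.shape(self.A)[1]
        self.D_diag = np.zeros(p)
        self.P_diag = np.ones(p)
        self.h2 = np.zeros(p)
        self.G2_diag = np.ones(p)
        super().__post_init__()


def cilds_smooth(params: CILDSParams, Y) -> SmootherResult:
    """Exact joint posterior over (c_t, z_t) and exact log likelihood.

    State layout: x_t[:q] = c_t; x_t[q:] = z_t for t >= 2 (x_1[q:] duplicates
    z_2).  Requires T >= 2 (there is no z_1).
    """
    Y = as_trials_array(Y)
    if Y.shape[2] < 2:
        raise ValueError("CILDS/CIFA need T >= 2 (the first latent is z_2)")
    return kalman_smooth(params.to_state_space(), Y)


def _em_update(params: CILDSParams, Y: np.ndarray, sm: SmootherResult,
               update_dynamics: bool) -> CILDSParams:
    """Closed-form constrained M-step from the augmented-state posterior."""
    q, p = params.q, params.p
    M = sm.means                       # (Btr, n, T)
    covs, lag = sm.covs, sm.lag_covs   # (T, n, n), (T-1, n, n)
    Btr, n, T = M.shape
    Mc, Mz = M[:, :q, :], M[:, q:, :]

    # ---- observation (B, R): y_t = B c_t + eps, t = 1..T -------------------
    cc_d = Btr * np.einsum("tjj->j", covs[:, :q, :q]) + np.einsum("bjt,bjt->j", Mc, Mc)
    yc_d = np.einsum("bjt,bjt->j", Y, Mc)
    yy_d = np.einsum("bjt,bjt->j", Y, Y)
    NT = Btr * T
    B_new = np.maximum(yc_d / cc_d, _GAMMA_EPS)
    R_new = floor_variances((yy_d - 2.0 * B_new * yc_d + B_new ** 2 * cc_d) / NT)

    # ---- calcium regression (Gamma, A, b, Q), t = 2..T ---------------------
    # response c_t; regressors [c_{t-1}, z_t, 1]; neurons decouple given diag Q
    cnt = Btr * (T - 1)
    # regressor second moments
    ccp_d = Btr * np.einsum("tjj->j", covs[:-1, :q, :q]) \
        + np.einsum("bjt,bjt->j", Mc[..., :-1], Mc[..., :-1])          # E[c_{t-1}^2]
    zcp = Btr * lag[:, q:, :q].sum(axis=0) \
        + np.einsum("bit,bjt->ij", Mz[..., 1:], Mc[..., :-1])           # (p, q) E[z_t c_{t-1}]
    zz = Btr * covs[1:, q:, q:].sum(axis=0) \
        + np.einsum("bit,bjt->ij", Mz[..., 1:], Mz[..., 1:])            # (p, p)
    z1 = Mz[..., 1:].sum(axis=(0, 2))                                    # (p,)
    cp1 = Mc[..., :-1].sum(axis=(0, 2))                                  # (q,)
    # response cross moments
    ccx_d = Btr * np.einsum("tjj->j", lag[:, :q, :q]) \
        + np.einsum("bjt,bjt->j", Mc[..., 1:], Mc[..., :-1])            # E[c_t c_{t-1}]
    cz = Btr * covs[1:, :q, q:].sum(axis=0) \
        + np.einsum("bjt,bit->ji", Mc[..., 1:], Mz[..., 1:])            # (q, p) E[c_t z_t]
    cc2_d = Btr * np.einsum("tjj->j", covs[1:, :q, :q]) \
        + np.einsum("bjt,bjt->j", Mc[..., 1:], Mc[..., 1:])             # E[c_t^2], t>=2
    c1s = Mc[..., 1:].sum(axis=(0, 2))                                   # (q,)

    Gam = np.empty(q)
    A_new = np.empty((q, p))
    b_new = np.empty(q)
    Q_new = np.empty(q)
    Gmat = np.empty((p + 2, p + 2))
    Gmat[1:p + 1, 1:p + 1] = zz
    Gmat[1:p + 1, p + 1] = z1
    Gmat[p + 1, 1:p + 1] = z1
    Gmat[p + 1, p + 1] = cnt
    for j in range(q):
        Gj = Gmat.copy()
        Gj[0, 0] = ccp_d[j]
        Gj[0, 1:p + 1] = zcp[:, j]
        Gj[1:p + 1, 0] = zcp[:, j]
        Gj[0, p + 1] = cp1[j]
        Gj[p + 1, 0] = cp1[j]
        rhs = np.concatenate([[ccx_d[j]], cz[j], [c1s[j]]])
        theta = np.linalg.solve(Gj, rhs)
        g = float(np.clip(theta[0], _GAMMA_EPS, 1.0 - _GAMMA_EPS))
        theta[0] = g
        Gam[j] = g
        A_new[j] = theta[1:p + 1]
        b_new[j] = theta[p + 1]
        Q_new[j] = (cc2_d[j] - 2.0 * theta @ rhs + theta @ Gj @ theta) / cnt
    Q_new = floor_variances(Q_new)

    # ---- initial calcium state --------------------------------------------
    m_c1 = Mc[:, :, 0]
    mu1 = m_c1.mean(axis=0)
    V1 = floor_variances(np.diag(covs[0][:q, :q]) + ((m_c1 - mu1) ** 2).mean(axis=0))

    new = replace(params, B_diag=B_new, R_diag=R_new, Gamma_diag=Gam,
                  A=A_new, b=b_new, Q_diag=Q_new, mu1=mu1, V1_diag=V1)

    if update_dynamics and T >= 3:
        # z_t = D z_{t-1} + v_t for t = 3..T: state pairs (t, t-1), t >= 2 here
        zz_prev = Btr * np.einsum("tii->i", covs[1:-1, q:, q:]) \
            + np.einsum("bit,bit->i", Mz[..., 1:-1], Mz[..., 1:-1])
        zz_cur = Btr * np.einsum("tii->i", covs[2:, q:, q:]) \
            + np.einsum("bit,bit->i", Mz[..., 2:], Mz[..., 2:])
        zcross = Btr * np.einsum("tii->i", lag[1:, q:, q:]) \
            + np.einsum("bit,bit->i", Mz[..., 2:], Mz[..., 1:-1])
        D_new = zcross / zz_prev
        P_new = floor_variances((zz_cur - 2.0 * D_new * zcross + D_new ** 2 * zz_prev)
                                / (Btr * (T - 2)))
        m_z2 = Mz[:, :, 1]
        h2 = m_z2.mean(axis=0)
        G2 = floor_variances(np.diag(covs[1][q:, q:]) + ((m_z2 - h2) ** 2).mean(axis=0))
        new = replace(new, D_diag=D_new, P_diag=P_new, h2=h2, G2_diag=G2)
    return new


def _run_em(params: CILDSParams, Y: np.ndarray, max_iter: int, tol: float,
            update_dynamics: bool, seed: int, model_id: str,
            extras: dict | None = None) -> FitReport:
    ll_trace = []
    converged = False
    for _ in range(max_iter):
        sm = cilds_smooth(params, Y)
        ll = sm.total_loglik
        ll_trace.append(ll)
        if len(ll_trace) > 1 and ll - ll_trace[-2] < tol:
            converged = True
            break
        params = _em_update(params, Y, sm, update_dynamics)
    return FitReport(params=params, loglik_trace=np.asarray(ll_trace),
                     n_iter=len(ll_trace), converged=converged, seed=seed,
                     model_id=model_id, extras=extras or {})


def _warm_start(data, p: int, seed: int, init_iters: int, dynamics: bool,
                deconv_opts: dict | None, two_stage_report: FitReport | None = None):
    """Warm start from a two-stage fit: per-neuron deconvolution, then a
    100-iteration LDS (or FA) on the stacked spike estimates.

    Mapping: B, R from the deconvolution gain and residual noise; Gamma from
    the fitted per-neuron decay; A, b, D, P, h, G from the second-stage latent
    model; Q from its independent-noise variances (the spiking variability the
    spike-level model attributes to each neuron).  An already-fitted two-stage
    report can be supplied instead of refitting.
    """
    from .deconv_lds import deconv_lds_fit, deconv_fa_fit
    from ..deconvolution import stack_calcium

    if two_stage_report is not None:
        rep = two_stage_report
    else:
        stage = deconv_lds_fit if dynamics else deconv_fa_fit
        rep = stage(data, p, max_iter=init_iters, seed=seed,
                    **(deconv_opts or {}))
    dec = rep.extras["deconv_results"]
    q = len(dec)
    B0 = np.array([max(r.params.a, 1e-3) for r in dec])
    R0 = floor_variances(np.array([max(r.residual_sd, 1e-3) ** 2 for r in dec]))
    Gam0 = np.array([r.params.gamma for r in dec])
    lds_p = rep.params
    Cal = stack_calcium(dec)                       # (trials, q, T)
    mu1 = Cal[:, :, 0].mean(axis=0)
    V1 = floor_variances(Cal[:, :, 0].var(axis=0) + 1e-3)
    Q0 = floor_variances(lds_p.R_diag)
    if dynamics:
        params = CILDSParams(
            B_diag=B0, R_diag=R0, Gamma_diag=Gam0, A=lds_p.A, b=lds_p.b,
            Q_diag=Q0, mu1=mu1, V1_diag=V1, D_diag=lds_p.D_diag,
            P_diag=lds_p.P_diag, h2=lds_p.h1, G2_diag=lds_p.G1_diag)
    else:
        params = CIFAParams(B_diag=B0, R_diag=R0, Gamma_diag=Gam0, A=lds_p.A,
                            b=lds_p.b, Q_diag=Q0, mu1=mu1, V1_diag=V1)
    return params, rep


def cilds_em(data, p: int, max_iter: int = 1500, tol: float = 1e-6,
             init: CILDSParams | None = None, seed: int = 0,
             init_iters: int = 100, deconv_opts: dict | None = None,
             warm_start_report: FitReport | None = None) -> FitReport:
    """Fit CILDS by EM, warm-started from a 100-iteration deconv-LDS fit
    (or from `warm_start_report`, an already-fitted deconv-LDS report)."""
    Y = as_trials_array(data)
    _, q, T = Y.shape
    if not (1 <= p < q):
        raise ValueError(f"need 1 <= p < q (got p={p}, q={q})")
    if T < 2:
        raise ValueError("CILDS needs T >= 2")
    extras = {}
    if init is None:
        init, warm = _warm_start(data, p, seed, init_iters, dynamics=True,
                                 deconv_opts=deconv_opts,
                                 two_stage_report=warm_start_report)
        extras["warm_start"] = warm
    return _run_em(init, Y, max_iter, tol, update_dynamics=True, seed=seed,
                   model_id="cilds", extras=extras)


def cifa_fit(data, p: int, max_iter: int = 1500, tol: float = 1e-6,
             init: CIFAParams | None = None, seed: int = 0,
             init_iters: int = 100, deconv_opts: dict | None = None) -> FitReport:
    """Fit CIFA by EM (same machinery as CILDS, latent prior fixed at N(0, I)),
    warm-started from a 100-iteration deconv-FA fit."""
    Y = as_trials_array(data)
    _, q, T = Y.shape
    if not (1 <= p < q):
        raise ValueError(f"need 1 <= p < q (got p={p}, q={q})")
    if T < 2:
        raise ValueError("CIFA needs T >= 2")
    extras = {}
    if init is None:
        init, warm = _warm_start(data, p, seed, init_iters, dynamics=False,
                                 deconv_opts=deconv_opts)
        extras["warm_start"] = warm
    return _run_em(init, Y, max_iter, tol, update_dynamics=False, seed=seed,
                   model_id="cifa", extras=extras)


def sample_cilds(params: CILDSParams, T: int, n_trials: int, seed: int = 0):
    """Draw from the generative model.

    Returns (Z, C, Y): Z (trials, p, T) with column 0 duplicating z_2 (there is
    no z_1), C (trials, q, T), Y (trials, q, T).
    """
    rng = np.random.default_rng(seed)
    X, Y = sample_state_space(params.to_state_space(), T, n_trials, rng)
    q = params.q
    return X[:, q:, :], X[:, :q, :], Y
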