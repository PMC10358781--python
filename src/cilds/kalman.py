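"""Batch Kalman filtering and RTS smoothing for linear-Gaussian state-space models.

All latent-variable models in this package (LDS, CILDS, CIFA) reduce to the
same linear-Gaussian chain

    x_1 ~ N(m0, S0)
    x_t = F x_{t-1} + d + w_t,   w_t ~ N(0, N),    t = 2..T
    y_t = H x_t + o + eps_t,     eps_t ~ N(0, diag(r))

optionally with a different (F1, d1, N1) on the first transition, which is how
the joint calcium/latent chain of CILDS is expressed.

Two structural facts keep EM cheap on many same-length trials: the covariance
recursions do not depend on the observations (run once, shared across trials,
with the mean recursions vectorized over trials), and for a time-invariant
model they converge to a steady state, after which the cached gain and
innovation factor are reused and the remaining sequential work runs in
compiled kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

_JITTER = 1e-9
_STEADY_RTOL = 1e-12


@dataclass
class StateSpace:
    """Time-invariant linear-Gaussian state-space model, with an optional
    distinct first transition.

    Shapes: state dim n, observation dim q.
    """

    F: np.ndarray  # (n, n) transition
    d: np.ndarray  # (n,) transition drive
    N: np.ndarray  # (n, n) process noise covariance (may be singular)
    H: np.ndarray  # (q, n) observation matrix
    o: np.ndarray  # (q,) observation offset
    r: np.ndarray  # (q,) diagonal observation noise variances
    m0: np.ndarray  # (n,) initial mean
    S0: np.ndarray  # (n, n) initial covariance
    F1: np.ndarray | None = None  # first-transition overrides
    d1: np.ndarray | None = None
    N1: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.F.shape[0]
        q = self.H.shape[0]
        if self.F.shape != (n, n) or self.N.shape != (n, n):
            raise ValueError("F and N must be square and conformable")
        if self.H.shape != (q, n):
            raise ValueError("H shape mismatch")
        if np.any(np.asarray(self.r) < 0):
            raise ValueError("observation noise variances must be >= 0")

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def q(self) -> int:
        return self.H.shape[0]

    def step_params(self, t: int):
        """Transition (F, d, N) taking x_{t-1} to x_t (t >= 1, 0-indexed)."""
        if t == 1 and self.F1 is not None:
            return self.F1, self.d1, self.N1
        return self.F, self.d, self.N


@dataclass
class SmootherResult:
    """Posterior moments from the RTS smoother, batched over trials.

    means:    (n_trials, n, T) posterior means E[x_t | y_1..T]
    covs:     (T, n, n) posterior covariances (shared across trials)
    lag_covs: (T-1, n, n) Cov(x_{t+1}, x_t | y_1..T), index t holds the pair (t+1, t)
    loglik:   (n_trials,) exact log data likelihood per trial
    """

    means: np.ndarray
    covs: np.ndarray
    lag_covs: np.ndarray
    loglik: np.ndarray
    filt_means: np.ndarray = field(repr=False, default=None)
    filt_covs: np.ndarray = field(repr=False, default=None)

    @property
    def total_loglik(self) -> float:
        return float(np.sum(self.loglik))


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def _chol_with_jitter(S: np.ndarray):
    """Cholesky with escalating jitter; hard error if still singular."""
    jitter = 0.0
    for _ in range(4):
        try:
            return cho_factor(S + jitter * np.eye(S.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = _JITTER if jitter == 0.0 else jitter * 1e3
    raise np.linalg.LinAlgError("innovation covariance is singular beyond repair")


# --------------------------------------------------------------------------
# compiled steady-region kernels (pure-Python definitions, jitted when numba
# is importable; behaviour is identical either way)


def _filter_means_steady(Y, m, FT, d, HT, o, KT, Sinv, logdet_const, fm, pm, ll):
    """Advance the mean recursion with frozen gain from t=0 of these arrays."""
    n_trials, q, T = Y.shape
    for t in range(T):
        m = m @ FT + d
        pm[:, :, t] = m
        nu = Y[:, :, t] - m @ HT - o
        quad = np.sum((nu @ Sinv) * nu, axis=1)
        ll -= 0.5 * (q * 1.8378770664093453 + logdet_const + quad)
        m = m + nu @ KT
        fm[:, :, t] = m
    return m


def _smoother_steady(fm, pm, JT, sm, sc, lag, fc_ss, pc_ss, J, t_lo):
    """Backward recursion for t = T-2 .. t_lo with constant smoother gain."""
    T = fm.shape[2]
    for t in range(T - 2, t_lo - 1, -1):
        sm[:, :, t] = fm[:, :, t] + (sm[:, :, t + 1] - pm[:, :, t + 1]) @ JT
        M = sc[t + 1] - pc_ss
        sc[t] = fc_ss + J @ M @ JT
        lag[t] = sc[t + 1] @ JT


try:
    from numba import njit as _njit

    _filter_means_steady = _njit(cache=False)(_filter_means_steady)
    _smoother_steady = _njit(cache=False)(_smoother_steady)
except ImportError:  # pragma: no cover
    pass


# --------------------------------------------------------------------------


def kalman_filter(model: StateSpace, Y: np.ndarray):
    """Forward pass.

    Parameters
    ----------
    Y : (n_trials, q, T) observations.

    Returns
    -------
    filt_means (n_trials, n, T), filt_covs (T, n, n),
    pred_means (n_trials, n, T), pred_covs (T, n, n), loglik (n_trials,),
    t_steady (first index from which the covariances are frozen, or T)
    """
    Y = np.ascontiguousarray(np.atleast_3d(Y), dtype=float)
    n_trials, q, T = Y.shape
    if q != model.q:
        raise ValueError(f"observation dim {q} does not match model ({model.q})")
    n = model.n
    H, o, r = model.H, model.o, np.asarray(model.r, dtype=float)

    fm = np.empty((n_trials, n, T))
    fc = np.empty((T, n, n))
    pm = np.empty((n_trials, n, T))
    pc = np.empty((T, n, n))
    ll = np.zeros(n_trials)
    log2pi = np.log(2.0 * np.pi)

    m = np.broadcast_to(model.m0, (n_trials, n)).copy()
    P = model.S0.copy()
    K = Sinv = None
    logdet = 0.0
    t_steady = T
    t = 0
    while t < T:
        if t > 0:
            F, d, N = model.step_params(t)
            m = m @ F.T + d
            P_pred = _symmetrize(F @ P @ F.T + N)
        else:
            P_pred = P
        # steady-state detection: the predicted covariance has converged and
        # the transition is past the (optional) distinct first step
        first_steady_ok = t >= (3 if model.F1 is not None else 2)
        if K is not None and first_steady_ok and \
                np.abs(P_pred - pc[t - 1]).max() < _STEADY_RTOL * (1.0 + np.abs(P_pred).max()):
            t_steady = t
            break
        pm[:, :, t] = m
        pc[t] = P_pred

        S = H @ P_pred @ H.T + np.diag(r)
        cf = _chol_with_jitter(S)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        PHt = P_pred @ H.T
        K = cho_solve(cf, PHt.T).T
        Sinv = cho_solve(cf, np.eye(q))
        nu = Y[:, :, t] - m @ H.T - o
        ll -= 0.5 * (q * log2pi + logdet + np.einsum("ij,jk,ik->i", nu, Sinv, nu))
        m = m + nu @ K.T
        P = _symmetrize(P_pred - K @ PHt.T)
        fm[:, :, t] = m
        fc[t] = P
        t += 1

    if t_steady < T:
        F, d, N = model.step_params(t_steady)
        fc[t_steady:] = fc[t_steady - 1]
        pc[t_steady:] = pc[t_steady - 1]
        # mean recursion from t_steady (prediction already applied above for
        # this t; rerun it inside the kernel from the last filtered mean)
        m_prev = fm[:, :, t_steady - 1].copy()
        _filter_means_steady(Y[:, :, t_steady:], m_prev,
                             np.ascontiguousarray(F.T), d,
                             np.ascontiguousarray(H.T), o,
                             np.ascontiguousarray(K.T),
                             np.ascontiguousarray(Sinv), logdet,
                             fm[:, :, t_steady:], pm[:, :, t_steady:], ll)
    return fm, fc, pm, pc, ll, t_steady


def kalman_smooth(model: StateSpace, Y: np.ndarray) -> SmootherResult:
    """Full forward-backward (RTS) pass returning exact posterior moments."""
    fm, fc, pm, pc, ll, t_steady = kalman_filter(model, Y)
    n_trials, n, T = fm.shape

    sm = np.empty_like(fm)
    sc = np.empty_like(fc)
    lag = np.empty((max(T - 1, 0), n, n))
    sm[:, :, -1] = fm[:, :, -1]
    sc[-1] = fc[-1]

    # steady region: constant smoother gain J = fc_ss F' pc_ss^{-1}
    t_lo = min(t_steady, T - 1)
    if t_lo < T - 1:
        F, _, _ = model.step_params(T - 1)
        cf = _chol_with_jitter(pc[T - 1])
        J = cho_solve(cf, F @ fc[T - 2]).T
        _smoother_steady(fm, pm, np.ascontiguousarray(J.T), sm, sc, lag,
                         np.ascontiguousarray(fc[T - 2]),
                         np.ascontiguousarray(pc[T - 1]),
                         np.ascontiguousarray(J), t_lo)
    for t in range(min(t_lo, T - 1) - 1, -1, -1):
        F, _, _ = model.step_params(t + 1)
        cf = _chol_with_jitter(pc[t + 1])
        J = cho_solve(cf, F @ fc[t]).T
        sm[:, :, t] = fm[:, :, t] + (sm[:, :, t + 1] - pm[:, :, t + 1]) @ J.T
        sc[t] = _symmetrize(fc[t] + J @ (sc[t + 1] - pc[t + 1]) @ J.T)
        lag[t] = sc[t + 1] @ J.T  # Cov(x_{t+1}, x_t | Y)
    return SmootherResult(means=sm, covs=sc, lag_covs=lag, loglik=ll,
                          filt_means=fm, filt_covs=fc)


def sample_state_space(model: StateSpace, T: int, n_trials: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, Y) from the generative model: X (n_trials, n, T), Y (n_trials, q, T)."""
    n, q = model.n, model.q
    X = np.empty((n_trials, n, T))
    L0 = np.linalg.cholesky(model.S0 + _JITTER * np.eye(n))
    X[:, :, 0] = model.m0 + rng.standard_normal((n_trials, n)) @ L0.T
    for t in range(1, T):
        F, d, N = model.step_params(t)
        # N may be singular: sample via eigen square root
        w, V = np.linalg.eigh(_symmetrize(N))
        Lw = V * np.sqrt(np.clip(w, 0.0, None))
        X[:, :, t] = X[:, :, t - 1] @ F.T + d + rng.standard_normal((n_trials, n)) @ Lw.T
    eps = rng.standard_normal((n_trials, q, T)) * np.sqrt(np.asarray(model.r))[None, :, None]
    Y = np.einsum("qn,bnt->bqt", model.H, X) + model.o[None, :, None] + eps
    return X, Y
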