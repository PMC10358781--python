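"""AR(1) constrained deconvolution of fluorescence traces (active-set / OASIS style).

Model per neuron:

    y_t = a c_t + b + eps_t,  eps_t ~ N(0, sigma^2)
    c_t = gamma c_{t-1} + s_t,   s_t >= 0

For fixed (a, b, gamma, lambda) the problem

    minimize 1/2 ||y - a c - b||^2 + lambda * sum_t s_t
    subject to s_t = c_t - gamma c_{t-1} >= 0 (t >= 2), c_1 >= 0

is a cone-constrained quadratic program solved exactly by pool-adjacent-violators
merging.  The L1 penalty is absorbed into the data (subtract
lambda*(1-gamma) from every point and lambda from the last), after which the
unpenalized pooling applies.  gamma / b / lambda / s_min can additionally be
optimized by coordinate descent (see the individual functions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import welch

__all__ = ["DeconvParams", "DeconvResult", "estimate_noise_sd",
           "deconvolve_ar1", "deconvolve_population", "kkt_residuals"]


@dataclass
class DeconvParams:
    """Per-neuron AR(1) deconvolution parameters."""

    gamma: float
    a: float = 1.0
    b: float = 0.0
    sigma: float | None = None   # noise sd; None -> estimated from the trace
    lam: float | None = None     # sparsity weight; None -> noise-constrained search
    s_min: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.a < 0:
            raise ValueError("gain a must be >= 0")
        if self.s_min < 0 or (self.lam is not None and self.lam < 0):
            raise ValueError("lambda and s_min must be >= 0")


@dataclass
class DeconvResult:
    """Deconvolution output for one neuron (one or more trials, concatenated
    results kept per trial)."""

    calcium: list[np.ndarray]
    spikes: list[np.ndarray]
    params: DeconvParams
    residual_sd: float
    flags: dict = field(default_factory=dict)

    @property
    def calcium_single(self) -> np.ndarray:
        return self.calcium[0]

    @property
    def spikes_single(self) -> np.ndarray:
        return self.spikes[0]


def estimate_noise_sd(y: np.ndarray, return_flag: bool = False):
    """Noise sd from the high-frequency power spectrum.

    Convention: square root of the mean power spectral density over the upper
    quartile of frequencies, where an AR(1) calcium signal has little power.
    Scale-equivariant; a constant trace returns 0 (flagged).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 32:
        raise ValueError("need a 1-D trace with at least 32 samples")
    if np.ptp(y) == 0:
        return (0.0, True) if return_flag else 0.0
    f, pxx = welch(y, nperseg=min(256, len(y)))
    sel = f >= 0.375  # upper quartile of [0, 0.5] cycles/sample
    sigma = float(np.sqrt(np.mean(pxx[sel]) / 2.0))
    return (sigma, False) if return_flag else sigma


def _pav_kernel(y, gamma, forced):
    """Stack-based pool-adjacent-violators pass.

    Pools are pushed left to right and merged while the decay constraint is
    violated (or the boundary is marked `forced`, which pins the constraint
    active for the s_min re-solve).  Pool values are finally clipped at zero,
    which is exact here because a negative-value pool can only survive merging
    when its predecessor is also clipped to zero.
    """
    T = len(y)
    v = np.empty(T)
    w = np.empty(T)
    st = np.empty(T, np.int64)
    ln = np.empty(T, np.int64)
    m = 0
    for t in range(T):
        v[m] = y[t]
        w[m] = 1.0
        st[m] = t
        ln[m] = 1
        m += 1
        while m >= 2:
            g = gamma ** ln[m - 2]
            if (not forced[st[m - 1]]) and v[m - 1] / w[m - 1] >= g * v[m - 2] / w[m - 2]:
                break
            v[m - 2] += g * v[m - 1]
            w[m - 2] += g * g * w[m - 1]
            ln[m - 2] += ln[m - 1]
            m -= 1
    c = np.empty(T)
    for i in range(m):
        val = v[i] / w[i]
        if val < 0.0:
            val = 0.0
        acc = val
        for k in range(ln[i]):
            c[st[i] + k] = acc
            acc *= gamma
    return c


try:  # compiled fast path; the pure-Python kernel is the reference behaviour
    from numba import njit as _njit

    _pav_kernel_jit = _njit(cache=False)(_pav_kernel)
except ImportError:  # pragma: no cover
    _pav_kernel_jit = _pav_kernel


def _oasis_pool(y: np.ndarray, gamma: float, forced: np.ndarray | None = None) -> np.ndarray:
    """Exact solution of min 1/2||y - c||^2 s.t. c_t >= gamma c_{t-1}, c_1 >= 0."""
    if forced is None:
        forced = np.zeros(len(y), dtype=np.bool_)
    return _pav_kernel_jit(np.ascontiguousarray(y, dtype=np.float64), float(gamma),
                           np.ascontiguousarray(forced, dtype=np.bool_))


def _solve_fixed(y: np.ndarray, gamma: float, lam: float, s_min: float) -> tuple[np.ndarray, np.ndarray]:
    """(c, s) for fixed gamma/lambda/s_min on a zero-baseline unit-gain trace."""
    T = len(y)
    pen = np.full(T, lam * (1.0 - gamma))
    pen[-1] = lam
    y_pen = y - pen
    forced = None
    for _ in range(20):
        c = _oasis_pool(y_pen, gamma, forced)
        s = np.empty(T)
        s[0] = c[0]
        s[1:] = c[1:] - gamma * c[:-1]
        small = (s > 0) & (s < s_min)
        small[0] = False
        if s_min <= 0 or not np.any(small):
            break
        forced = small if forced is None else (forced | small)
    s[np.abs(s) < 1e-12] = 0.0
    return c, s


def kkt_residuals(y_pen: np.ndarray, c: np.ndarray, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Dual variables and complementary-slackness products for a solution of
    the pooled problem on the penalty-absorbed trace `y_pen`.

    Returns (nu, nu * s): optimality requires nu >= 0 (dual feasibility) and
    nu * s ~ 0 (complementary slackness).
    """
    T = len(c)
    g = c - y_pen
    nu = np.empty(T)
    nu[-1] = g[-1]
    for t in range(T - 2, -1, -1):
        nu[t] = g[t] + gamma * nu[t + 1]
    s = np.empty(T)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    return nu, nu * s


def _multi_solve(traces, gamma, lam, s_min, a, b):
    """Solve each trial independently on the normalized trace (y-b)/a."""
    cs, ss, rss, n = [], [], 0.0, 0
    for y in traces:
        yn = (y - b) / a
        c, s = _solve_fixed(yn, gamma, lam / (a * a) if lam > 0 else 0.0, s_min)
        cs.append(c)
        ss.append(s)
        rss += float(np.sum((y - a * c - b) ** 2))
        n += len(y)
    return cs, ss, np.sqrt(rss / n)


def _auto_lambda(traces, gamma, s_min, a, b, sigma, max_iter: int = 25):
    """Smallest lambda whose residual RMS reaches the noise estimate (binary
    search; residual RMS is nondecreasing in lambda)."""
    lo, hi = 0.0, 1.0
    cs, ss, rms = _multi_solve(traces, gamma, 0.0, s_min, a, b)
    if rms >= sigma:
        return 0.0, cs, ss, rms
    for _ in range(60):
        cs, ss, rms = _multi_solve(traces, gamma, hi, s_min, a, b)
        if rms >= sigma:
            break
        hi *= 4.0
    lam = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cs, ss, rms = _multi_solve(traces, gamma, mid, s_min, a, b)
        if rms < sigma:
            lo = mid
        else:
            hi = mid
        lam = mid
        if hi - lo < 1e-6 * (1.0 + hi):
            break
    return lam, cs, ss, rms


def deconvolve_ar1(y, params: DeconvParams, optimize: frozenset | set | tuple = ()) -> DeconvResult:
    """Deconvolve one neuron's fluorescence.

    Parameters
    ----------
    y : 1-D trace or list of per-trial traces (each solved with c_0 = 0).
    params : initial/fixed parameters; `params.lam is None` selects the
        noise-constrained mode in which lambda is tuned until the residual RMS
        matches the estimated noise sd.
    optimize : subset of {"gamma", "b", "s_min"}; coordinate descent with at
        most 10 outer rounds ("gamma" line-searched on (0.5, 0.9999) by
        residual sum of squares, "b" as the residual mean, "s_min" over a small
        grid by residual criterion).
    """
    traces = [np.asarray(t, float) for t in (y if isinstance(y, (list, tuple)) else [y])]
    optimize = set(optimize)
    p = replace(params)
    flags: dict = {}

    concat = np.concatenate(traces)
    if np.ptp(concat) == 0:
        cs = [np.zeros_like(t) for t in traces]
        return DeconvResult(cs, [c.copy() for c in cs],
                            replace(p, b=float(concat[0]) if len(concat) else 0.0,
                                    sigma=0.0, lam=p.lam or 0.0),
                            0.0, {"constant_trace": True, "zero_noise": True})

    if p.sigma is None:
        sig, const = estimate_noise_sd(concat, return_flag=True) if len(concat) >= 32 else (float(np.std(concat)), False)
        p.sigma = sig
        if const:
            flags["zero_noise"] = True

    def solve(pp):
        if pp.lam is None:
            lam, cs, ss, rms = _auto_lambda(traces, pp.gamma, pp.s_min, pp.a, pp.b, pp.sigma)
            return replace(pp, lam=lam), cs, ss, rms
        cs, ss, rms = _multi_solve(traces, pp.gamma, pp.lam, pp.s_min, pp.a, pp.b)
        return pp, cs, ss, rms

    n_rounds = 10 if optimize else 1
    fitted, cs, ss, rms = solve(p)
    for _ in range(n_rounds - 1):
        prev = (fitted.gamma, fitted.b, fitted.s_min)
        if "b" in optimize:
            resid_mean = float(np.mean([np.mean(t - fitted.a * c) for t, c in zip(traces, cs)]))
            fitted = replace(fitted, b=resid_mean)
        if "gamma" in optimize:
            # line search at the current (frozen) lambda; lambda is re-selected
            # once per outer round after gamma settles
            lam_frozen = fitted.lam if fitted.lam is not None else 0.0

            def rss_of(g):
                _, _, r = _multi_solve(traces, float(g), lam_frozen,
                                       fitted.s_min, fitted.a, fitted.b)
                return r
            res = minimize_scalar(rss_of, bounds=(0.5, 0.9999), method="bounded",
                                  options={"xatol": 1e-3})
            fitted = replace(fitted, gamma=float(res.x))
        if "s_min" in optimize:
            grid = [0.0, 0.25 * p.sigma, 0.5 * p.sigma, p.sigma, 2 * p.sigma]
            best, best_rms = fitted.s_min, np.inf
            for sm in grid:
                pp = replace(fitted, s_min=sm, lam=p.lam)
                _, _, _, r = solve(pp)
                if r < best_rms:
                    best, best_rms = sm, r
            fitted = replace(fitted, s_min=best)
        fitted, cs, ss, rms = solve(replace(fitted, lam=p.lam))
        if np.allclose(prev, (fitted.gamma, fitted.b, fitted.s_min), atol=1e-4):
            break

    return DeconvResult(cs, ss, fitted, rms, flags)


def deconvolve_population(Y: np.ndarray, params_template: DeconvParams | None = None,
                          gamma: float | np.ndarray = 0.98,
                          optimize: frozenset | set | tuple = (),
                          lam: float | None = None) -> list[DeconvResult]:
    """Independent per-neuron deconvolution of a (q, T) or (trials, q, T) array.

    Returns one DeconvResult per neuron, order-aligned with the neuron axis.
    Per-neuron failures are re-raised with the neuron index attached.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 2:
        Y = Y[None]
    _, q, _ = Y.shape
    gam = np.broadcast_to(np.asarray(gamma, float), (q,))
    results = []
    for j in range(q):
        base = (replace(params_template, gamma=float(gam[j])) if params_template is not None
                else DeconvParams(gamma=float(gam[j]), lam=lam))
        traces = [Y[tr, j] for tr in range(Y.shape[0])]
        try:
            results.append(deconvolve_ar1(traces, base, optimize))
        except Exception as exc:  # annotate with neuron index, re-raise
            raise RuntimeError(f"deconvolution failed for neuron {j}: {exc}") from exc
    return results


def stack_spikes(results: list[DeconvResult]) -> np.ndarray:
    """(n_trials, q, T) array of spike estimates from per-neuron results."""
    n_trials = len(results[0].spikes)
    return np.stack([np.stack([r.spikes[tr] for r in results]) for tr in range(n_trials)])


def stack_calcium(results: list[DeconvResult]) -> np.ndarray:
    n_trials = len(results[0].calcium)
    return np.stack([np.stack([r.calcium[tr] for r in results]) for tr in range(n_trials)])
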