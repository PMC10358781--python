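"""Two-stage baselines: per-neuron deconvolution followed by LDS (or FA) on
the stacked spike estimates."""

from __future__ import annotations

import numpy as np

from ..deconvolution import DeconvParams, deconvolve_population, stack_spikes
from .base import FitReport, as_trials_array
from .fa import fa_fit
from .lds import lds_em

__all__ = ["deconv_lds_fit", "deconv_fa_fit"]


def _stage_one(Y: np.ndarray, gamma, optimize, lam, s_min, deconv_results=None):
    if deconv_results is not None:
        return deconv_results, stack_spikes(deconv_results)
    template = DeconvParams(gamma=float(np.atleast_1d(gamma)[0]), lam=lam, s_min=s_min)
    dec = deconvolve_population(Y, params_template=template, gamma=gamma,
                                optimize=optimize)
    return dec, stack_spikes(dec)


def deconv_lds_fit(data, p: int, max_iter: int = 1500, tol: float = 1e-6,
                   seed: int = 0, gamma: float | np.ndarray = 0.98,
                   optimize: tuple = ("gamma", "b"), lam: float | None = None,
                   s_min: float = 0.0, fa_iters: int = 1000,
                   deconv_results=None) -> FitReport:
    """deconv-LDS: each neuron is deconvolved independently (stage 1), then an
    LDS is fit to the spike estimates of all neurons (stage 2).

    The returned FitReport carries the stage-2 LDS parameters;
    ``extras["deconv_results"]`` retains the per-neuron stage-1 output and
    ``extras["spike_estimates"]`` the stacked (trials, q, T) spike array.
    """
    Y = as_trials_array(data)
    dec, S = _stage_one(Y, gamma, optimize, lam, s_min, deconv_results)
    rep = lds_em(S, p, max_iter=max_iter, tol=tol, seed=seed, fa_iters=fa_iters)
    rep.model_id = "deconv-lds"
    rep.extras["deconv_results"] = dec
    rep.extras["spike_estimates"] = S
    return rep


def deconv_fa_fit(data, p: int, max_iter: int = 1000, tol: float = 1e-6,
                  seed: int = 0, gamma: float | np.ndarray = 0.98,
                  optimize: tuple = ("gamma", "b"), lam: float | None = None,
                  s_min: float = 0.0, deconv_results=None) -> FitReport:
    """deconv-FA: per-neuron deconvolution, then factor analysis on the spike
    estimates (used to warm-start CIFA)."""
    Y = as_trials_array(data)
    dec, S = _stage_one(Y, gamma, optimize, lam, s_min, deconv_results)
    rep = fa_fit(S, p, max_iter=max_iter, tol=tol, seed=seed)
    rep.model_id = "deconv-fa"
    rep.extras["deconv_results"] = dec
    rep.extras["spike_estimates"] = S
    return rep
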