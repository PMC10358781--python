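"""Uniform dispatch over the model family: latent estimation on new data and
leave-neuron-out fluorescence prediction."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ..deconvolution import deconvolve_ar1, stack_spikes
from .base import FitReport, LatentTrajectories, as_trials_array
from .cilds import CILDSParams, cilds_smooth
from .fa import FAParams, fa_posterior_mean
from .lds import LDSParams, lds_smooth

__all__ = ["MODEL_IDS", "estimate_latents", "predict_heldout_neuron"]

MODEL_IDS = ("lds", "deconv-lds", "cilds", "cifa", "fa")


def _params_of(fit):
    return fit.params if isinstance(fit, FitReport) else fit


def _check(model_id: str, fit) -> None:
    if model_id not in MODEL_IDS:
        raise TypeError(f"unknown model_id {model_id!r}")
    params = _params_of(fit)
    expected = {"lds": LDSParams, "deconv-lds": LDSParams,
                "cilds": CILDSParams, "cifa": CILDSParams, "fa": FAParams}[model_id]
    if not isinstance(params, expected):
        raise TypeError(f"model {model_id!r} expects {expected.__name__}, "
                        f"got {type(params).__name__}")


def _deconvolve_with_fitted(fit: FitReport, Y: np.ndarray) -> np.ndarray:
    """Deconvolve new data with the per-neuron parameters fitted in stage 1."""
    dec = fit.extras.get("deconv_results")
    if dec is None:
        raise TypeError("deconv-lds requires the FitReport from deconv_lds_fit "
                        "(per-neuron deconvolution parameters are needed)")
    results = []
    for j, r in enumerate(dec):
        pj = replace(r.params, lam=r.params.lam or 0.0)
        traces = [Y[tr, j] for tr in range(Y.shape[0])]
        results.append(deconvolve_ar1(traces, pj, optimize=()))
    return stack_spikes(results), results


def estimate_latents(model_id: str, fit, data) -> LatentTrajectories:
    """Per-trial posterior-mean latent time courses for any fitted model.

    `fit` is a FitReport (required for deconv-lds) or a bare parameter set.
    Trials are processed independently; for CILDS/CIFA the calcium posterior
    E[c_t | Y] is returned alongside the latents.
    """
    _check(model_id, fit)
    params = _params_of(fit)
    Y = as_trials_array(data)

    if model_id == "lds":
        sm = lds_smooth(params, Y)
        return LatentTrajectories(sm.means, np.einsum("tii->ti", sm.covs),
                                  model_id=model_id)
    if model_id == "deconv-lds":
        S, _ = _deconvolve_with_fitted(fit, Y)
        sm = lds_smooth(params, S)
        return LatentTrajectories(sm.means, np.einsum("tii->ti", sm.covs),
                                  model_id=model_id)
    if model_id in ("cilds", "cifa"):
        q = params.q
        sm = cilds_smooth(params, Y)
        return LatentTrajectories(sm.means[:, q:, :],
                                  np.einsum("tii->ti", sm.covs[:, q:, q:]),
                                  c_mean=sm.means[:, :q, :],
                                  c_var=np.einsum("tii->ti", sm.covs[:, :q, :q]),
                                  model_id=model_id)
    # fa
    Zm = fa_posterior_mean(params, Y)
    A, R = params.A, params.R_diag
    post_cov = np.linalg.inv(np.eye(params.p) + (A.T / R) @ A)
    var = np.broadcast_to(np.diag(post_cov), (Y.shape[2], params.p)).copy()
    return LatentTrajectories(Zm, var, model_id=model_id)


def _drop_lds(params: LDSParams, j: int) -> LDSParams:
    keep = np.arange(params.q) != j
    return replace(params, A=params.A[keep], b=params.b[keep],
                   R_diag=params.R_diag[keep])


def _drop_cilds(params: CILDSParams, j: int) -> CILDSParams:
    keep = np.arange(params.q) != j
    return replace(params, B_diag=params.B_diag[keep], R_diag=params.R_diag[keep],
                   Gamma_diag=params.Gamma_diag[keep], A=params.A[keep],
                   b=params.b[keep], Q_diag=params.Q_diag[keep],
                   mu1=params.mu1[keep], V1_diag=params.V1_diag[keep])


def _ar_propagate(c0: float, gamma: float, drive: np.ndarray) -> np.ndarray:
    """c_t = gamma c_{t-1} + drive_t, t >= 2, with c_1 = c0. drive has length T
    (drive[0] unused)."""
    c = np.empty_like(drive)
    c[0] = c0
    for t in range(1, len(drive)):
        c[t] = gamma * c[t - 1] + drive[t]
    return c


def predict_heldout_neuron(model_id: str, fit, Y_minus_j: np.ndarray, j: int) -> np.ndarray:
    """Predict neuron j's fluorescence from the other q-1 neurons.

    Latents are inferred under the submodel with neuron j's observation rows
    deleted; the prediction maps the posterior-mean latents back through
    neuron j's observation parameters (for CILDS/CIFA via the deterministic
    AR(1) calcium recursion driven by A_j z_t + b_j, for deconv-LDS via the
    fitted deconvolution kernel).

    Y_minus_j : (trials, q-1, T) or (q-1, T). Returns (trials, T) (squeezed to
    (T,) for 2-D input).
    """
    _check(model_id, fit)
    params = _params_of(fit)
    squeeze = np.asarray(Y_minus_j).ndim == 2
    Y = as_trials_array(Y_minus_j)
    if params.q < 2:
        raise ValueError("cannot hold out a neuron from a single-neuron model")
    if Y.shape[1] != params.q - 1:
        raise ValueError("Y_minus_j must have q-1 neurons")

    if model_id in ("lds", "fa"):
        if model_id == "lds":
            z = lds_smooth(_drop_lds(params, j), Y).means
        else:
            sub = FAParams(A=np.delete(params.A, j, axis=0),
                           b=np.delete(params.b, j), R_diag=np.delete(params.R_diag, j))
            z = fa_posterior_mean(sub, Y)
        pred = np.einsum("p,bpt->bt", params.A[j], z) + params.b[j]
    elif model_id == "deconv-lds":
        dec = fit.extras.get("deconv_results")
        if dec is None:
            raise TypeError("deconv-lds prediction requires the deconv_lds_fit report")
        sub_dec = [r for k, r in enumerate(dec) if k != j]
        results = []
        for k, r in enumerate(sub_dec):
            pk = replace(r.params, lam=r.params.lam or 0.0)
            results.append(deconvolve_ar1([Y[tr, k] for tr in range(Y.shape[0])],
                                          pk, optimize=()))
        S = stack_spikes(results)
        z = lds_smooth(_drop_lds(params, j), S).means
        s_hat = np.einsum("p,bpt->bt", params.A[j], z) + params.b[j]
        pj = dec[j].params
        pred = np.stack([
            pj.a * _ar_propagate(max(s[0], 0.0), pj.gamma, s) + pj.b for s in s_hat])
        # AR start: c_1 = s_1 (zero pre-trial calcium), as in the forward model
    else:  # cilds / cifa
        sub = _drop_cilds(params, j)
        sm = cilds_smooth(sub, Y)
        z = sm.means[:, sub.q:, :]
        drive = np.einsum("p,bpt->bt", params.A[j], z) + params.b[j]
        pred = np.stack([
            _ar_propagate(params.mu1[j], params.Gamma_diag[j], d) for d in drive])
        pred = params.B_diag[j] * pred
    return pred[0] if squeeze else pred
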