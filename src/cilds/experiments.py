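"""Scaled-down simulation studies packaged as reusable experiments.

Each function runs one self-contained study end to end (simulate, fit,
evaluate) at desk scale and returns plain dictionaries of numbers.  The
problem sizes are deliberately smaller than the reference design (fewer,
shorter trials and capped EM iterations) so a study completes in minutes on
one CPU; docs/methods.md records the sizes used.
"""

from __future__ import annotations

import numpy as np

from .evaluation import align_latents
from .models import (CILDSParams, cifa_fit, cilds_em, deconv_lds_fit,
                     estimate_latents, lds_em, sample_cilds)
from .simulation import SimulationConfig, simulate_dataset

__all__ = ["method_comparison_replicate", "cilds_parameter_recovery",
           "cifa_decay_bias_sweep", "fitted_decay_tau_ms"]

# EM iteration caps for the scaled studies (the library default for a full
# analysis remains the convergence rule with up to 1500 iterations)
_LDS_ITERS = 150
_CILDS_ITERS = 150
_INIT_ITERS = 100


def method_comparison_replicate(seed: int, timescale_ms: float = 200.0,
                                q: int = 20, p: int = 4, n_trials: int = 10,
                                trial_length_s: float = 10.0,
                                noise_regime: str = "medium",
                                indicator: str = "gcamp6f",
                                models: tuple = ("lds", "deconv-lds", "cilds")) -> dict:
    """One replicate of the method comparison: simulate a train/test pair,
    fit each model on the training set, estimate latents on the test set, and
    score mean aligned R^2 against the ground-truth latents.

    The per-neuron deconvolution (stage 1) is shared between deconv-LDS and
    the CILDS warm start, as both use the same stage-1 output.
    """
    cfg = SimulationConfig(p=p, q=q, timescale_ms=timescale_ms,
                           n_trials=n_trials, trial_length_s=trial_length_s,
                           noise_regime=noise_regime, indicator=indicator,
                           seed=seed)
    (train, _), (test, gt_test) = simulate_dataset(cfg)
    Y, Yte = train.fluorescence, test.fluorescence
    gamma0 = cfg.decay_per_step ** cfg.downsample_factor

    out = {}
    rep_dlds = None
    if "deconv-lds" in models or "cilds" in models:
        rep_dlds = deconv_lds_fit(Y, p, max_iter=_LDS_ITERS, seed=seed,
                                  gamma=gamma0)
    for model_id in models:
        if model_id == "lds":
            rep = lds_em(Y, p, max_iter=_LDS_ITERS, seed=seed)
        elif model_id == "deconv-lds":
            rep = rep_dlds
        elif model_id == "cilds":
            rep = cilds_em(Y, p, max_iter=_CILDS_ITERS, seed=seed,
                           warm_start_report=rep_dlds)
        else:
            raise ValueError(model_id)
        traj = estimate_latents(model_id, rep, Yte)
        out[model_id] = float(align_latents(traj.z_mean, gt_test.latents).r2.mean())
    return out


def _recovery_ground_truth(q: int, p: int, gamma: float, seed: int) -> CILDSParams:
    """A well-conditioned CILDS parameter set used as simulation ground truth:
    slow calcium decay, smooth unit-variance latents, moderate noise."""
    rng = np.random.default_rng(seed)
    D = np.array([0.99, 0.95])[:p] if p <= 2 else rng.uniform(0.9, 0.99, p)
    return CILDSParams(
        B_diag=np.ones(q),
        R_diag=np.full(q, 0.2),
        Gamma_diag=np.full(q, gamma),
        A=rng.standard_normal((q, p)) * 0.3,
        b=np.full(q, 0.05),
        Q_diag=np.full(q, 0.05),
        mu1=np.full(q, 2.0),
        V1_diag=np.full(q, 0.5),
        D_diag=D, P_diag=1.0 - D ** 2,
        h2=np.zeros(p), G2_diag=np.ones(p))


def cilds_parameter_recovery(seed: int, q: int = 20, p: int = 2,
                             n_trials: int = 40, T: int = 400,
                             gamma: float = 0.98, max_iter: int = 150) -> dict:
    """Fit CILDS to data drawn from a known CILDS and measure how well the
    per-neuron calcium decay and the latent time courses are recovered."""
    truth = _recovery_ground_truth(q, p, gamma, seed)
    Z, C, Y = sample_cilds(truth, T, n_trials, seed=seed + 1)
    rep = cilds_em(Y, p, max_iter=max_iter, seed=seed, init_iters=_INIT_ITERS,
                   deconv_opts={"gamma": min(gamma, 0.98)})
    traj = estimate_latents("cilds", rep, Y)
    res = align_latents(traj.z_mean, Z)
    return {
        "gamma_true": gamma,
        "gamma_max_abs_error": float(np.abs(rep.params.Gamma_diag - gamma).max()),
        "aligned_latent_r2": float(res.r2.mean()),
        "loglik_monotone": bool(rep.check_monotone()),
    }


def fitted_decay_tau_ms(gamma_diag: np.ndarray, imaging_rate_hz: float) -> float:
    """Median per-neuron decay time constant (ms) implied by per-frame decays."""
    g = np.clip(np.asarray(gamma_diag, float), 1e-6, 1 - 1e-9)
    dt_ms = 1000.0 / imaging_rate_hz
    return float(np.median(-dt_ms / np.log(g)))


def cifa_decay_bias_sweep(seed: int, timescales_ms=(50.0, 200.0, 1000.0, 5000.0),
                          q: int = 20, p: int = 4, n_trials: int = 8,
                          trial_length_s: float = 20.0, indicator: str = "gcamp6s",
                          n_rep: int = 3, max_iter: int = 200) -> dict:
    """How the fitted calcium decay depends on the latent timescale.

    With the true decay held fixed, a model without latent dynamics (CIFA) can
    only explain slowly varying fluorescence by inflating its calcium decay,
    so its fitted time constant grows with the latent timescale; CILDS, whose
    latent dynamics absorb the slow variation, stays near the truth.

    The decay/latent-timescale confound is expressed most strongly when the
    indicator kinetics overlap the latent timescales, so this study uses a
    slow indicator by default (with a fast one the inflation saturates once
    the latents are much slower than the decay).  Fitted time constants are
    averaged over `n_rep` independent simulations per timescale.
    """
    taus_cifa, taus_cilds = [], []
    true_tau = None
    for i, ts in enumerate(timescales_ms):
        tc, tl = [], []
        for rep in range(n_rep):
            cfg = SimulationConfig(p=p, q=q, timescale_ms=float(ts),
                                   n_trials=n_trials, trial_length_s=trial_length_s,
                                   noise_regime="medium", indicator=indicator,
                                   seed=seed + 1000 * i + 97 * rep)
            (train, _), _ = simulate_dataset(cfg)
            Y = train.fluorescence
            gamma0 = cfg.decay_per_step ** cfg.downsample_factor
            true_tau = -(1000.0 / cfg.imaging_rate_hz) / np.log(gamma0)
            rep_dlds = deconv_lds_fit(Y, p, max_iter=_INIT_ITERS, seed=seed,
                                      gamma=gamma0)
            dec = rep_dlds.extras["deconv_results"]
            rep_cilds = cilds_em(Y, p, max_iter=max_iter, seed=seed,
                                 warm_start_report=rep_dlds)
            rep_cifa = cifa_fit(Y, p, max_iter=max_iter, seed=seed,
                                init_iters=_INIT_ITERS,
                                deconv_opts={"gamma": gamma0,
                                             "deconv_results": dec})
            tl.append(fitted_decay_tau_ms(rep_cilds.params.Gamma_diag,
                                          cfg.imaging_rate_hz))
            tc.append(fitted_decay_tau_ms(rep_cifa.params.Gamma_diag,
                                          cfg.imaging_rate_hz))
        taus_cilds.append(float(np.mean(tl)))
        taus_cifa.append(float(np.mean(tc)))
    return {
        "timescales_ms": list(timescales_ms),
        "true_decay_tau_ms": float(true_tau),
        "cifa_tau_ms": taus_cifa,
        "cilds_tau_ms": taus_cilds,
    }
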