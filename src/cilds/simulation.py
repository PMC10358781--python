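"""Generative simulation of calcium-imaging fluorescence from known latents.

The pipeline mirrors how shared low-dimensional activity reaches a microscope:

1. p independent Gaussian processes with squared-exponential covariance
   (unit marginal variance) define the latent time courses z_t at 1 ms
   resolution.
2. Rates are obtained through a softplus readout log(1 + exp(W z_t + mu)).
3. Binary spikes are drawn per 1 ms bin as Bernoulli(1 - exp(-rate * dt)),
   the exact thinning of an inhomogeneous Poisson process to a binary train.
4. Calcium follows an AR(1) recursion c_t = Gamma c_{t-1} + s_t per neuron,
   with per-indicator decay.
5. Fluorescence y_t = B c_t + b + eps with diagonal Gaussian noise, then
   down-sampled (non-overlapping bin means) to the imaging rate.

Every sampler is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.special import roots_hermitenorm
from scipy.optimize import brentq

__all__ = [
    "GPKernelSpec", "SimulationConfig", "GroundTruthBundle", "StimulusSchedule",
    "sample_gp_latents", "latents_to_rates", "sample_spikes",
    "spikes_to_fluorescence", "downsample", "make_loading_matrix",
    "simulate_dataset", "simulate_stimulus_dataset",
    "INDICATOR_DECAY_TAU_MS", "NOISE_REGIME_SNR",
]

# Approximate fluorescence decay time constants (ms) for common GCaMP variants.
# These are order-of-magnitude conventions for the indicator literature and are
# fully overridable through SimulationConfig.decay_tau_ms.
INDICATOR_DECAY_TAU_MS = {"gcamp6f": 200.0, "gcamp6m": 500.0, "gcamp6s": 1000.0}

# Noise regimes defined by per-neuron fluorescence SNR (signal sd / noise sd)
# at the imaging rate.  Approximate convention, overridable via target_snr.
NOISE_REGIME_SNR = {"low": 10.0, "medium": 3.0, "high": 1.0}

_CHOLESKY_MAX_T = 4096


@dataclass(frozen=True)
class GPKernelSpec:
    """Squared-exponential GP kernel K(dt) = sf2 * exp(-dt^2 / (2 tau^2)) + sn2 * delta."""

    timescale_ms: float
    noise_variance: float = 1e-9
    signal_variance: float | None = None  # default: 1 - noise_variance (unit marginal)

    def __post_init__(self):
        if self.timescale_ms <= 0:
            raise ValueError("GP timescale must be positive")
        if self.noise_variance <= 0:
            raise ValueError("GP noise variance must be strictly positive")

    @property
    def sf2(self) -> float:
        return 1.0 - self.noise_variance if self.signal_variance is None else self.signal_variance


@dataclass
class StimulusSchedule:
    """Grating presentation schedule: K = |orientations| x |spatial frequencies|
    classes shown back-to-back in random order, `repeats` times each per trial."""

    orientations_deg: np.ndarray
    spatial_freqs_cpd: np.ndarray
    onsets: np.ndarray           # (n_presentations,) time-point indices, imaging rate
    labels: np.ndarray           # (n_presentations,) class labels in 1..K
    duration_timepoints: int
    repeats_per_class: int

    @property
    def n_classes(self) -> int:
        return len(self.orientations_deg) * len(self.spatial_freqs_cpd)

    def validate(self, trial_timepoints: int) -> None:
        order = np.argsort(self.onsets)
        on, dur = self.onsets[order], self.duration_timepoints
        if np.any(on[1:] < on[:-1] + dur):
            raise ValueError("presentations overlap within a trial")
        if np.any(on + dur > trial_timepoints) or np.any(on < 0):
            raise ValueError("presentation window exits the trial")


@dataclass
class SimulationConfig:
    """All knobs for one simulated dataset.

    Defaults follow the reference simulation design: p = 10 unit-variance GP
    latents at 1 kHz, softplus rates, binary Poisson spikes, indicator-specific
    AR(1) calcium, identity gain, zero baseline, 100 trials of 60 s imaged at
    40 Hz.
    """

    p: int = 10
    q: int = 94
    timescale_ms: float = 200.0
    n_trials: int = 100
    trial_length_s: float = 60.0
    generation_rate_hz: float = 1000.0
    imaging_rate_hz: float = 40.0
    noise_regime: str = "medium"
    indicator: str = "gcamp6f"
    target_rate_hz: float = 10.0
    column_norm_range: tuple[float, float] = (0.5, 1.5)
    gp_noise_variance: float = 1e-9
    decay_tau_ms: float | None = None     # override indicator default
    target_snr: float | None = None       # override noise-regime default
    downsample_method: str = "mean"       # or "decimate"
    seed: int = 0
    # explicit parameter overrides (else derived from the fields above)
    W: np.ndarray | None = None
    mu: np.ndarray | None = None
    gamma: np.ndarray | None = None       # per-neuron per-step decay, diagonal of Gamma
    B_diag: np.ndarray | None = None
    baseline: np.ndarray | None = None
    R_diag: np.ndarray | None = None

    def __post_init__(self):
        if self.p < 1 or self.q <= self.p:
            raise ValueError("need q > p >= 1")
        factor = self.generation_rate_hz / self.imaging_rate_hz
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("generation_rate_hz must be divisible by imaging_rate_hz")
        if self.noise_regime not in NOISE_REGIME_SNR and self.target_snr is None:
            raise ValueError(f"unknown noise regime {self.noise_regime!r}")
        if self.indicator not in INDICATOR_DECAY_TAU_MS and self.decay_tau_ms is None:
            raise ValueError(f"unknown indicator {self.indicator!r}")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.generation_rate_hz

    @property
    def downsample_factor(self) -> int:
        return int(round(self.generation_rate_hz / self.imaging_rate_hz))

    @property
    def timepoints_per_trial_gen(self) -> int:
        return int(round(self.trial_length_s * self.generation_rate_hz))

    @property
    def timepoints_per_trial(self) -> int:
        """Imaging-rate time points per trial."""
        return int(round(self.trial_length_s * self.imaging_rate_hz))

    @property
    def decay_per_step(self) -> float:
        tau = self.decay_tau_ms if self.decay_tau_ms is not None else INDICATOR_DECAY_TAU_MS[self.indicator]
        return float(np.exp(-self.dt_ms / tau))

    @property
    def snr(self) -> float:
        return self.target_snr if self.target_snr is not None else NOISE_REGIME_SNR[self.noise_regime]


@dataclass
class GroundTruthBundle:
    """Everything the simulator knows that an experimenter would not."""

    latents: np.ndarray            # (n_trials, p, T) at imaging rate (bin means)
    latents_gen: np.ndarray | None  # (n_trials, p, T_gen) at generation rate, or None
    spikes: np.ndarray | None      # (n_trials, q, T_gen) binary
    calcium: np.ndarray | None     # (n_trials, q, T_gen)
    fluorescence_gen: np.ndarray | None  # (n_trials, q, T_gen) pre-downsampling
    W: np.ndarray
    mu: np.ndarray
    gamma: np.ndarray
    R_diag: np.ndarray


def sample_gp_latents(kernels: list[GPKernelSpec], T: int, dt_ms: float,
                      seed: int | np.random.Generator) -> np.ndarray:
    """Draw one zero-mean stationary GP per kernel; rows independent.

    Uses exact Cholesky sampling for T <= 4096 and circulant-embedding FFT
    sampling for longer sequences (exact up to clipping of numerically
    negative embedding eigenvalues, which are negligible for this kernel once
    the diagonal noise term is included).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    Z = np.empty((len(kernels), T))
    for i, k in enumerate(kernels):
        lags = np.arange(T) * dt_ms
        row = k.sf2 * np.exp(-0.5 * (lags / k.timescale_ms) ** 2)
        row[0] += k.noise_variance
        if T <= _CHOLESKY_MAX_T:
            from scipy.linalg import toeplitz, cholesky
            K = toeplitz(row)
            L = cholesky(K + 1e-12 * np.eye(T), lower=True)
            Z[i] = L @ rng.standard_normal(T)
        else:
            Z[i] = _sample_circulant(k, T, dt_ms, rng)
    return Z


def _sample_circulant(k: GPKernelSpec, T: int, dt_ms: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Circulant-embedding sampler for a stationary covariance first row."""
    pad = int(np.ceil(6.0 * k.timescale_ms / dt_ms))
    M = 2 * (T + pad)
    c = np.zeros(M)
    ext = np.arange(T + pad) * dt_ms
    vals = k.sf2 * np.exp(-0.5 * (ext / k.timescale_ms) ** 2)
    vals[0] += k.noise_variance
    c[: T + pad] = vals
    c[T + pad + 1:] = vals[1:][::-1]
    lam = np.clip(np.fft.fft(c).real, 0.0, None)
    # complex spectral sampling: Re(sqrt(M) * ifft(sqrt(lam) * xi)) has
    # covariance exactly circulant(c) for standard complex normal xi
    xi = rng.standard_normal(M) + 1j * rng.standard_normal(M)
    draw = (np.fft.ifft(np.sqrt(lam) * xi) * np.sqrt(M)).real
    return draw[:T]


def _as_diag_vector(M, q: int, name: str) -> np.ndarray:
    """Accept a length-q diagonal vector, a scalar, or a strictly diagonal
    q x q matrix; reject anything with off-diagonal structure."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 2:
        if M.shape != (q, q) or np.any(M != np.diag(np.diag(M))):
            raise ValueError(f"{name} must be strictly diagonal")
        return np.diag(M).copy()
    return np.broadcast_to(M, (q,)).astype(float)


def latents_to_rates(Z: np.ndarray, W: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Softplus readout: rates (spikes/s) = log(1 + exp(W z_t + mu)), elementwise."""
    Z, W, mu = np.asarray(Z), np.asarray(W), np.asarray(mu)
    if W.shape[1] != Z.shape[0] or W.shape[0] != mu.shape[0]:
        raise ValueError("shape mismatch between W, Z, mu")
    x = W @ Z + mu[:, None]
    return np.logaddexp(0.0, x)


def sample_spikes(rates: np.ndarray, dt_ms: float,
                  seed: int | np.random.Generator) -> np.ndarray:
    """Binary spikes: per-bin Bernoulli with p = 1 - exp(-rate * dt)."""
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = 1.0 - np.exp(-rates * (dt_ms / 1000.0))
    return (rng.random(rates.shape) < p).astype(np.int8)


def spikes_to_fluorescence(S: np.ndarray, gamma: np.ndarray, B_diag: np.ndarray,
                           baseline: np.ndarray, R_diag: np.ndarray,
                           seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """AR(1) calcium c_t = gamma c_{t-1} + s_t (c_0 = 0) and noisy fluorescence
    y_t = B c_t + b + eps, eps ~ N(0, diag(R)).

    gamma, B_diag, R_diag may be vectors (the diagonals) or diagonal matrices;
    a non-diagonal matrix is a constraint violation.
    """
    S = np.asarray(S)
    q, T = S.shape
    gamma = _as_diag_vector(gamma, q, "Gamma")
    B_diag = _as_diag_vector(B_diag, q, "B")
    R_diag = _as_diag_vector(R_diag, q, "R")
    gamma = np.broadcast_to(np.asarray(gamma, float), (q,))
    if np.any(gamma <= 0) or np.any(gamma >= 1):
        raise ValueError("calcium decay must lie in (0, 1)")
    if np.any(np.asarray(R_diag) < 0):
        raise ValueError("noise variances must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    C = np.empty((q, T))
    for j in range(q):
        C[j] = lfilter([1.0], [1.0, -gamma[j]], S[j].astype(float))
    Y = B_diag[:, None] * C + np.asarray(baseline)[:, None]
    Y = Y + rng.standard_normal((q, T)) * np.sqrt(np.asarray(R_diag))[:, None]
    return C, Y


def downsample(Y: np.ndarray, factor: int, method: str = "mean") -> np.ndarray:
    """Reduce the time axis by `factor`: non-overlapping bin means (default)
    or decimation (every factor-th sample)."""
    Y = np.asarray(Y)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    T = Y.shape[-1]
    if T % factor != 0:
        raise ValueError(f"time length {T} not divisible by factor {factor}")
    if factor == 1:
        return Y.copy()
    if method == "mean":
        return Y.reshape(*Y.shape[:-1], T // factor, factor).mean(axis=-1)
    if method == "decimate":
        return Y[..., factor - 1::factor].copy()
    raise ValueError(f"unknown downsampling method {method!r}")


def _softplus_mean_rate(sigma: float, mu: float, nodes, weights) -> float:
    """E[softplus(sigma * x + mu)] for x ~ N(0,1), Gauss-Hermite quadrature."""
    return float(weights @ np.logaddexp(0.0, sigma * nodes + mu))


def make_loading_matrix(q: int, p: int, target_rate_hz: float = 10.0,
                        column_norm_range: tuple[float, float] = (0.5, 1.5),
                        seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic loading matrix W (q x p) with Gaussian rows scaled to the given
    column-norm range, and offsets mu solved per neuron so that the expected
    softplus rate under unit-variance latents equals `target_rate_hz`."""
    if not (q > p >= 1):
        raise ValueError("need q > p >= 1")
    if target_rate_hz <= 0:
        raise ValueError("target mean rate must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    W = rng.standard_normal((q, p))
    norms = np.linalg.norm(W, axis=0)
    # column norms u_k * sqrt(q) give each neuron a latent drive of sd
    # ~ sqrt(sum_k u_k^2): rate modulation of the same order as the mean rate,
    # as in strongly tuned cortical populations
    targets = rng.uniform(*column_norm_range, size=p) * np.sqrt(q)
    W *= targets / norms
    nodes, weights = roots_hermitenorm(64)
    weights = weights / weights.sum()
    mu = np.empty(q)
    for j in range(q):
        sig = np.linalg.norm(W[j])
        f = lambda m: _softplus_mean_rate(sig, m, nodes, weights) - target_rate_hz
        mu[j] = brentq(f, -200.0, 200.0)
    return W, mu


def _resolve_params(cfg: SimulationConfig, rng: np.random.Generator):
    """Fill in W, mu, gamma, B, b from the config, drawing what is unspecified."""
    if cfg.W is not None:
        W = np.asarray(cfg.W, float)
        mu = np.asarray(cfg.mu, float) if cfg.mu is not None else np.zeros(cfg.q)
    else:
        W, mu = make_loading_matrix(cfg.q, cfg.p, cfg.target_rate_hz,
                                    cfg.column_norm_range, rng)
    gamma = (np.asarray(cfg.gamma, float) if cfg.gamma is not None
             else np.full(cfg.q, cfg.decay_per_step))
    B_diag = np.asarray(cfg.B_diag, float) if cfg.B_diag is not None else np.ones(cfg.q)
    baseline = np.asarray(cfg.baseline, float) if cfg.baseline is not None else np.zeros(cfg.q)
    return W, mu, gamma, B_diag, baseline


def _noise_for_snr(cfg: SimulationConfig, signal_imaging: np.ndarray) -> np.ndarray:
    """Diagonal fluorescence noise variances at generation rate chosen so the
    per-neuron SNR at the imaging rate (after bin-mean downsampling, which
    shrinks the noise sd by sqrt(factor)) equals cfg.snr."""
    sd = signal_imaging.std(axis=-1)
    sd = np.maximum(sd, 1e-12)
    return cfg.downsample_factor * (sd / cfg.snr) ** 2


def _simulate_half(cfg: SimulationConfig, W, mu, gamma, B_diag, baseline,
                   rng: np.random.Generator, R_diag: np.ndarray | None,
                   latent_shift: np.ndarray | None = None):
    """One long trace -> n_trials trials. Returns imaging-rate Y and truth arrays."""
    T_gen = cfg.timepoints_per_trial_gen * cfg.n_trials
    kernels = [GPKernelSpec(cfg.timescale_ms, cfg.gp_noise_variance) for _ in range(cfg.p)]
    Z = sample_gp_latents(kernels, T_gen, cfg.dt_ms, rng)
    if latent_shift is not None:
        Z = Z + latent_shift
    rates = latents_to_rates(Z, W, mu)
    S = sample_spikes(rates, cfg.dt_ms, rng)
    # noiseless calcium/fluorescence first, so noise can be set from signal sd
    C, Y0 = spikes_to_fluorescence(S, gamma, B_diag, baseline,
                                   np.zeros(cfg.q), rng)
    if R_diag is None:
        sig_img = downsample(Y0, cfg.downsample_factor, cfg.downsample_method)
        R_diag = _noise_for_snr(cfg, sig_img)
    Y = Y0 + rng.standard_normal(Y0.shape) * np.sqrt(R_diag)[:, None]
    Y_img = downsample(Y, cfg.downsample_factor, cfg.downsample_method)
    Z_img = downsample(Z, cfg.downsample_factor, cfg.downsample_method)

    def split(arr):  # (d, T_total) -> (n_trials, d, T_trial)
        d, Ttot = arr.shape
        return arr.reshape(d, cfg.n_trials, Ttot // cfg.n_trials).transpose(1, 0, 2)

    return split(Y_img), split(Z_img), split(Z), split(S), split(C), split(Y), R_diag


def simulate_dataset(cfg: SimulationConfig, keep_generation_rate: bool = False):
    """Simulate matched training and test sets.

    Two independent long traces (one for training, one for testing) are
    generated per neuron from the same parameters, then divided into
    cfg.n_trials trials each, exactly mirroring a train/test recording split.

    Returns
    -------
    (train, test) : each a (FluorescenceDataset, GroundTruthBundle) pair.
    """
    from .io import FluorescenceDataset

    rng = np.random.default_rng(cfg.seed)
    W, mu, gamma, B_diag, baseline = _resolve_params(cfg, rng)
    R_diag = np.asarray(cfg.R_diag, float) if cfg.R_diag is not None else None

    out = []
    for part in ("train", "test"):
        Yi, Zi, Zg, S, C, Yg, R_used = _simulate_half(
            cfg, W, mu, gamma, B_diag, baseline, rng, R_diag)
        R_diag = R_used  # test half reuses the training noise level
        ds = FluorescenceDataset(
            fluorescence=Yi, sampling_rate_hz=cfg.imaging_rate_hz,
            neuron_ids=[f"n{j:03d}" for j in range(cfg.q)],
            meta={"part": part, "seed": cfg.seed, "indicator": cfg.indicator,
                  "noise_regime": cfg.noise_regime, "timescale_ms": cfg.timescale_ms})
        gt = GroundTruthBundle(
            latents=Zi, latents_gen=Zg if keep_generation_rate else None,
            spikes=S if keep_generation_rate else None,
            calcium=C if keep_generation_rate else None,
            fluorescence_gen=Yg if keep_generation_rate else None,
            W=W, mu=mu, gamma=gamma, R_diag=R_used)
        out.append((ds, gt))
    return tuple(out)


def make_grating_schedule(n_orientations: int = 12, n_spatial_freqs: int = 15,
                          repeats_per_class: int = 4, duration_timepoints: int = 10,
                          start_timepoint: int = 0,
                          seed: int | np.random.Generator = 0) -> StimulusSchedule:
    """Back-to-back presentation schedule: every class `repeats_per_class`
    times per trial in random order, 250 ms-style fixed duration windows."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    K = n_orientations * n_spatial_freqs
    labels = np.repeat(np.arange(1, K + 1), repeats_per_class)
    rng.shuffle(labels)
    onsets = start_timepoint + np.arange(len(labels)) * duration_timepoints
    return StimulusSchedule(
        orientations_deg=np.linspace(0.0, 165.0, n_orientations),
        spatial_freqs_cpd=np.linspace(0.02, 0.30, n_spatial_freqs),
        onsets=onsets, labels=labels,
        duration_timepoints=duration_timepoints,
        repeats_per_class=repeats_per_class)


def simulate_stimulus_dataset(cfg: SimulationConfig, schedule: StimulusSchedule,
                              class_effects: np.ndarray,
                              seed: int | np.random.Generator | None = None):
    """Simulate a dataset whose latent means shift by a class-dependent vector
    during each presentation window.

    class_effects : (K, p) latent-mean shift per class (zero rows -> no label
    information).  The schedule's label order is re-randomized per trial.
    Returns (FluorescenceDataset, list of per-trial StimulusSchedule, GroundTruthBundle).
    """
    from .io import FluorescenceDataset

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    class_effects = np.atleast_2d(np.asarray(class_effects, float))
    if class_effects.shape != (schedule.n_classes, cfg.p):
        raise ValueError("class_effects must be (K, p)")
    schedule.validate(cfg.timepoints_per_trial)

    W, mu, gamma, B_diag, baseline = _resolve_params(cfg, rng)
    factor = cfg.downsample_factor
    T_trial_gen = cfg.timepoints_per_trial_gen

    # per-trial randomized label order, shared onsets
    schedules = []
    shift = np.zeros((cfg.p, T_trial_gen * cfg.n_trials))
    for tr in range(cfg.n_trials):
        labels = schedule.labels.copy()
        rng.shuffle(labels)
        sched = replace(schedule, labels=labels)
        schedules.append(sched)
        for onset, lab in zip(sched.onsets, labels):
            lo = tr * T_trial_gen + onset * factor
            hi = lo + sched.duration_timepoints * factor
            shift[:, lo:hi] += class_effects[lab - 1][:, None]

    cfg_one = replace(cfg)  # same config; single (training) half with shifts
    Yi, Zi, Zg, S, C, Yg, R_used = _simulate_half(
        cfg_one, W, mu, gamma, B_diag, baseline, rng,
        np.asarray(cfg.R_diag, float) if cfg.R_diag is not None else None,
        latent_shift=shift)
    ds = FluorescenceDataset(
        fluorescence=Yi, sampling_rate_hz=cfg.imaging_rate_hz,
        neuron_ids=[f"n{j:03d}" for j in range(cfg.q)],
        trial_labels=None,
        meta={"seed": cfg.seed, "stimulus": True})
    gt = GroundTruthBundle(latents=Zi, latents_gen=None, spikes=None, calcium=None,
                           fluorescence_gen=None, W=W, mu=mu, gamma=gamma, R_diag=R_used)
    return ds, schedules, gt
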