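"""Shared containers and helpers for the model fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VAR_FLOOR = 1e-9


@dataclass
class FitReport:
    """Outcome of one EM fit."""

    params: object
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int | None = None
    model_id: str = ""
    extras: dict = field(default_factory=dict)

    def check_monotone(self, rel_tol: float = 1e-8) -> bool:
        ll = np.asarray(self.loglik_trace)
        if len(ll) < 2:
            return True
        slack = rel_tol * np.maximum(np.abs(ll[:-1]), 1.0)
        return bool(np.all(np.diff(ll) >= -slack))


@dataclass
class LatentTrajectories:
    """Posterior-mean latent time courses, one block per trial."""

    z_mean: np.ndarray              # (n_trials, p, T)
    z_var: np.ndarray               # (T, p) marginal posterior variances
    c_mean: np.ndarray | None = None  # (n_trials, q, T) for CILDS/CIFA
    c_var: np.ndarray | None = None
    model_id: str = ""


def as_trials_array(data) -> np.ndarray:
    """Accept a FluorescenceDataset, a (trials, q, T) array, or a (q, T) array."""
    from ..io import FluorescenceDataset

    if isinstance(data, FluorescenceDataset):
        Y = data.fluorescence
    else:
        Y = np.asarray(data, dtype=float)
        if Y.ndim == 2:
            Y = Y[None]
    if Y.ndim != 3:
        raise ValueError("expected (n_trials, q, T) data")
    if not np.all(np.isfinite(Y)):
        raise ValueError("data contain non-finite values")
    return Y


def floor_variances(v: np.ndarray, floor: float = VAR_FLOOR) -> np.ndarray:
    return np.maximum(np.asarray(v, float), floor)
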