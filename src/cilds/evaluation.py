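"""Evaluation machinery: latent alignment and R^2, leave-neuron-out prediction
with paired significance tests, cross-validation scaffolding, and Gaussian
Naive Bayes stimulus decoding with lag selection.

Latent variables from any of the models are only identified up to an
invertible linear remixing, so estimated latents are first aligned to the
reference by least squares (W = Z Z~' (Z~ Z~')^{-1}), with W fit on one inner
half of the test trials and applied to the other, before computing a
per-latent cross-validated R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AlignmentResult", "FoldSpec", "PredictionReport", "DecoderParams",
    "make_folds", "align_latents", "r2_per_latent", "aligned_r2",
    "lno_evaluate", "paired_compare", "window_features", "gnb_fit",
    "gnb_decode", "gnb_posteriors", "gnb_cross_validate", "select_decoding_lag",
    "select_dimensionality", "compare_likelihoods",
]


# --------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class FoldSpec:
    assignment: np.ndarray   # (n_trials,) fold index in 0..k-1
    k: int
    seed: int

    def train_trials(self, fold: int) -> np.ndarray:
        return np.where(self.assignment != fold)[0]

    def test_trials(self, fold: int) -> np.ndarray:
        return np.where(self.assignment == fold)[0]


def make_folds(n_trials: int, k: int, seed: int = 0) -> FoldSpec:
    """Seeded random partition of trials into k folds of near-equal size."""
    if k > n_trials:
        raise ValueError(f"cannot make {k} folds from {n_trials} trials")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    assignment = np.empty(n_trials, dtype=int)
    assignment[perm] = np.arange(n_trials) % k
    return FoldSpec(assignment=assignment, k=k, seed=seed)


# --------------------------------------------------------------------------
# alignment and R^2


@dataclass
class AlignmentResult:
    W_per_half: list[np.ndarray]       # transformation fitted on each inner half
    Z_hat: np.ndarray                  # (p, T~) aligned estimates, halves pooled
    Z_true: np.ndarray                 # matching reference, halves pooled
    r2: np.ndarray                     # (p,) per-latent R^2
    rank_deficient: bool = False
    half_slices: list = field(default_factory=list)


def _lstsq_map(Z: np.ndarray, Z_tilde: np.ndarray) -> tuple[np.ndarray, bool]:
    """W = (Z Z~')(Z~ Z~')^{-1}; pseudo-inverse on rank deficiency (flagged)."""
    G = Z_tilde @ Z_tilde.T
    C = Z @ Z_tilde.T
    if np.linalg.matrix_rank(G) < G.shape[0]:
        return C @ np.linalg.pinv(G), True
    return np.linalg.solve(G.T, C.T).T, False


def r2_per_latent(z_true: np.ndarray, z_hat: np.ndarray) -> float:
    """R^2 = 1 - sum (z - zhat)^2 / sum (z - zbar)^2; may be negative for
    cross-validated estimates."""
    z_true = np.asarray(z_true, float).ravel()
    z_hat = np.asarray(z_hat, float).ravel()
    if len(z_true) != len(z_hat) or len(z_true) < 2:
        raise ValueError("need equal-length series of length >= 2")
    ss_tot = float(np.sum((z_true - z_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant reference latent")
    return 1.0 - float(np.sum((z_true - z_hat) ** 2)) / ss_tot


def align_latents(Z_est: np.ndarray, Z_true: np.ndarray,
                  inner_split: int | None = None) -> AlignmentResult:
    """Align estimated to reference latents with an inner-half cross-fit.

    Z_est, Z_true : (p, T~) time-concatenated latents for one test fold, or
    (n_trials, p, T) stacks (then the trial list is split in half).  W is fit
    on one inner half and applied to the other, in both directions; results
    are pooled before computing per-latent R^2.
    """
    Z_est, Z_true = np.asarray(Z_est, float), np.asarray(Z_true, float)
    if Z_est.shape != Z_true.shape:
        raise ValueError("estimated and reference latents must match in shape")
    if Z_est.ndim == 3:
        n_half = Z_est.shape[0] // 2 if inner_split is None else inner_split
        halves = [np.concatenate(list(Z_est[:n_half]), axis=1),
                  np.concatenate(list(Z_est[n_half:]), axis=1)]
        truths = [np.concatenate(list(Z_true[:n_half]), axis=1),
                  np.concatenate(list(Z_true[n_half:]), axis=1)]
    else:
        T = Z_est.shape[1]
        cut = T // 2 if inner_split is None else inner_split
        halves = [Z_est[:, :cut], Z_est[:, cut:]]
        truths = [Z_true[:, :cut], Z_true[:, cut:]]
    p = Z_est.shape[-2]
    if min(h.shape[1] for h in halves) <= p:
        raise ValueError("too few time points per inner half for alignment")

    Ws, rank_flag = [], False
    for h, tr in zip(halves, truths):
        W, deficient = _lstsq_map(tr, h)
        Ws.append(W)
        rank_flag |= deficient
    # apply each half's W to the *other* half, pool
    Zhat = np.concatenate([Ws[1] @ halves[0], Ws[0] @ halves[1]], axis=1)
    Ztr = np.concatenate([truths[0], truths[1]], axis=1)
    r2 = np.array([r2_per_latent(Ztr[i], Zhat[i]) for i in range(p)])
    return AlignmentResult(W_per_half=Ws, Z_hat=Zhat, Z_true=Ztr, r2=r2,
                           rank_deficient=rank_flag)


def aligned_r2(Z_est: np.ndarray, Z_true: np.ndarray) -> float:
    """Mean per-latent R^2 after inner-half alignment (scalar summary)."""
    return float(align_latents(Z_est, Z_true).r2.mean())


# --------------------------------------------------------------------------
# leave-neuron-out


@dataclass
class PredictionReport:
    correlations: np.ndarray    # (q, n_trials), NaN where undefined
    model_id: str = ""
    flags: dict = field(default_factory=dict)

    @property
    def per_neuron_mean(self) -> np.ndarray:
        return np.nanmean(self.correlations, axis=1)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def lno_evaluate(model_id: str, dataset, p: int, folds: FoldSpec,
                 fit_fn=None, **fit_kwargs) -> PredictionReport:
    """Leave-neuron-out fluorescence prediction over a k-fold trial split.

    For each fold, the model is fit on the training trials; on each validation
    trial every neuron is held out in turn, latents are inferred from the
    remaining neurons and the held-out trace is predicted; Pearson correlation
    is recorded per neuron and trial.  Cells with a zero-variance predicted or
    recorded trace are NaN-flagged and excluded from means.
    """
    from .models import (cifa_fit, cilds_em, deconv_lds_fit, lds_em,
                         predict_heldout_neuron)

    fitters = {"lds": lds_em, "deconv-lds": deconv_lds_fit,
               "cilds": cilds_em, "cifa": cifa_fit}
    if fit_fn is None:
        fit_fn = fitters[model_id]
    Y = dataset.fluorescence if hasattr(dataset, "fluorescence") else np.asarray(dataset)
    n_trials, q, T = Y.shape
    corr = np.full((q, n_trials), np.nan)
    n_undefined = 0
    for fold in range(folds.k):
        tr_idx, te_idx = folds.train_trials(fold), folds.test_trials(fold)
        fit = fit_fn(Y[tr_idx], p, **fit_kwargs)
        for j in range(q):
            keep = np.arange(q) != j
            pred = predict_heldout_neuron(model_id, fit, Y[te_idx][:, keep, :], j)
            for i, trial in enumerate(te_idx):
                r = _pearson(pred[i], Y[trial, j])
                if np.isnan(r):
                    n_undefined += 1
                corr[j, trial] = r
    return PredictionReport(correlations=corr, model_id=model_id,
                            flags={"n_undefined": n_undefined})


def paired_compare(report_a: PredictionReport, report_b: PredictionReport) -> dict:
    """Paired two-tailed t-tests: per neuron across trials, and across the
    neuron population on trial-means."""
    A, B = report_a.correlations, report_b.correlations
    if A.shape != B.shape:
        raise ValueError("reports must have matched neurons and trials")
    q = A.shape[0]
    t_per, p_per = np.full(q, np.nan), np.full(q, np.nan)
    for j in range(q):
        ok = ~(np.isnan(A[j]) | np.isnan(B[j]))
        d = A[j, ok] - B[j, ok]
        if len(d) < 2:
            continue  # p undefined, left NaN
        if np.std(d, ddof=1) == 0:
            if np.all(d == 0):  # identical: no difference at all
                t_per[j], p_per[j] = 0.0, 1.0
            continue  # constant nonzero difference: p undefined, left NaN
        t_per[j], p_per[j] = stats.ttest_rel(A[j, ok], B[j, ok])
    ma, mb = report_a.per_neuron_mean, report_b.per_neuron_mean
    ok = ~(np.isnan(ma) | np.isnan(mb))
    if ok.sum() >= 2 and np.std(ma[ok] - mb[ok], ddof=1) > 0:
        t_pop, p_pop = stats.ttest_rel(ma[ok], mb[ok])
    elif ok.sum() >= 2 and np.all(ma[ok] == mb[ok]):
        t_pop, p_pop = 0.0, 1.0
    else:
        t_pop, p_pop = np.nan, np.nan
    # Benjamini-Hochberg column, an extension beyond the raw per-neuron tests
    finite = np.where(~np.isnan(p_per))[0]
    p_bh = np.full(q, np.nan)
    if len(finite):
        order = np.argsort(p_per[finite])
        ranked = p_per[finite][order] * len(finite) / (np.arange(len(finite)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        p_bh[finite[order]] = np.clip(ranked, 0, 1)
    return {"t_per_neuron": t_per, "p_per_neuron": p_per, "p_bh": p_bh,
            "t_population": float(t_pop), "p_population": float(p_pop)}


# --------------------------------------------------------------------------
# decoding


@dataclass
class DecoderParams:
    class_means: np.ndarray   # (K, p)
    var_diag: np.ndarray      # (p,) shared diagonal covariance
    classes: np.ndarray       # (K,) labels
    lag: int = 0

    def __post_init__(self):
        if np.any(self.var_diag <= 0):
            raise ValueError("decoder variances must be positive")


def window_features(latents: np.ndarray, schedules, lag: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean latent in each (lag-shifted) presentation window.

    latents : (n_trials, p, T); schedules : one StimulusSchedule per trial (or
    a single schedule reused).  Windows shifted beyond the trial are dropped.
    Returns (features (n, p), labels (n,)).
    """
    latents = np.asarray(latents, float)
    n_trials, p, T = latents.shape
    if not isinstance(schedules, (list, tuple)):
        schedules = [schedules] * n_trials
    feats, labs = [], []
    for tr, sched in zip(range(n_trials), schedules):
        for onset, lab in zip(sched.onsets, sched.labels):
            lo = onset + lag
            hi = lo + sched.duration_timepoints
            if lo < 0 or hi > T:
                continue  # dropped: window exits the trial
            feats.append(latents[tr, :, lo:hi].mean(axis=1))
            labs.append(lab)
    return np.asarray(feats), np.asarray(labs)


def gnb_fit(features: np.ndarray, labels: np.ndarray,
            classes: np.ndarray | None = None, lag: int = 0) -> DecoderParams:
    """Gaussian Naive Bayes with per-class means and one shared diagonal
    covariance (pooled within-class variances), maximum likelihood."""
    X = np.atleast_2d(np.asarray(features, float))
    y = np.asarray(labels)
    classes = np.unique(y) if classes is None else np.asarray(classes)
    missing = set(classes) - set(np.unique(y))
    if missing:
        raise ValueError(f"classes missing from training data: {sorted(missing)}")
    K, p = len(classes), X.shape[1]
    mu = np.empty((K, p))
    pooled = np.zeros(p)
    for k, c in enumerate(classes):
        Xk = X[y == c]
        mu[k] = Xk.mean(axis=0)
        pooled += np.sum((Xk - mu[k]) ** 2, axis=0)
    var = np.maximum(pooled / len(X), 1e-12)
    return DecoderParams(class_means=mu, var_diag=var, classes=classes, lag=lag)


def gnb_posteriors(params: DecoderParams, features: np.ndarray) -> np.ndarray:
    """P(C_k | z) under uniform class priors, shape (n, K)."""
    X = np.atleast_2d(np.asarray(features, float))
    if X.shape[1] != params.class_means.shape[1]:
        raise ValueError("feature dimension does not match the decoder")
    logp = -0.5 * ((X[:, None, :] - params.class_means[None, :, :]) ** 2
                   / params.var_diag).sum(-1)
    logp -= logp.max(axis=1, keepdims=True)
    w = np.exp(logp)
    return w / w.sum(axis=1, keepdims=True)


def gnb_decode(params: DecoderParams, features: np.ndarray,
               labels: np.ndarray | None = None):
    """Argmax-posterior classification under uniform class priors; ties go to
    the lowest class index.  Returns predictions, and accuracy if labels given."""
    X = np.atleast_2d(np.asarray(features, float))
    if X.shape[1] != params.class_means.shape[1]:
        raise ValueError("feature dimension does not match the decoder")
    # log N(x | mu_k, diag(var)); shared covariance -> linear discriminants
    d2 = ((X[:, None, :] - params.class_means[None, :, :]) ** 2 / params.var_diag).sum(-1)
    pred = params.classes[np.argmin(d2, axis=1)]  # argmin of d2 = argmax posterior
    if labels is None:
        return pred
    return pred, float(np.mean(pred == np.asarray(labels)))


def gnb_cross_validate(features: np.ndarray, labels: np.ndarray, k: int = 5,
                       seed: int = 0) -> float:
    """k-fold cross-validated GNB accuracy over presentations."""
    X, y = np.asarray(features, float), np.asarray(labels)
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, int)
    assignment[perm] = np.arange(n) % k
    correct = 0
    for fold in range(k):
        tr, te = assignment != fold, assignment == fold
        dec = gnb_fit(X[tr], y[tr], classes=np.unique(y))
        pred = gnb_decode(dec, X[te])
        correct += int(np.sum(pred == y[te]))
    return correct / n


def select_decoding_lag(latents: np.ndarray, schedules, lag_grid,
                        k: int = 5, seed: int = 0) -> tuple[int, np.ndarray]:
    """Lag maximizing cross-validated decoding accuracy; ties -> smallest lag."""
    lag_grid = list(lag_grid)
    if not lag_grid:
        raise ValueError("empty lag grid")
    acc = np.empty(len(lag_grid))
    for i, lag in enumerate(lag_grid):
        X, y = window_features(latents, schedules, lag)
        acc[i] = gnb_cross_validate(X, y, k=k, seed=seed)
    best = lag_grid[int(np.argmax(acc))]  # argmax returns first max: smallest lag
    return best, acc


# --------------------------------------------------------------------------
# model selection


def compare_likelihoods(ll_by_model: dict) -> dict:
    """Within-model likelihood comparison only.  Data likelihoods are not on a
    common scale across model families, so any request mixing model ids is
    refused."""
    ids = set(ll_by_model)
    if len(ids) > 1:
        raise ValueError(
            "cross-model likelihood comparison refused: data likelihoods are "
            f"not comparable across methods (got {sorted(ids)}); compare "
            "dimensionalities within one model, or use leave-neuron-out "
            "prediction to compare methods")
    return ll_by_model


def _cv_loglik(Y: np.ndarray, model_id: str, p: int, folds: FoldSpec,
               fit_kwargs: dict) -> float:
    from .models import (cifa_fit, cilds_em, cilds_smooth, deconv_lds_fit,
                         lds_em, lds_smooth)

    total = 0.0
    for fold in range(folds.k):
        tr, te = folds.train_trials(fold), folds.test_trials(fold)
        if model_id == "lds":
            fit = lds_em(Y[tr], p, **fit_kwargs)
            total += lds_smooth(fit.params, Y[te]).total_loglik
        elif model_id == "deconv-lds":
            fit = deconv_lds_fit(Y[tr], p, **fit_kwargs)
            from .models.dispatch import _deconvolve_with_fitted
            S, _ = _deconvolve_with_fitted(fit, Y[te])
            total += lds_smooth(fit.params, S).total_loglik
        elif model_id in ("cilds", "cifa"):
            fit = (cilds_em if model_id == "cilds" else cifa_fit)(Y[tr], p, **fit_kwargs)
            total += cilds_smooth(fit.params, Y[te]).total_loglik
        else:
            raise ValueError(f"unknown model {model_id!r}")
    return total


def select_dimensionality(dataset, model_id: str, p_grid, folds: FoldSpec,
                          **fit_kwargs) -> tuple[int, dict]:
    """Latent dimensionality maximizing the cross-validated data likelihood,
    within one model family (nested-CV inner loop)."""
    p_grid = list(p_grid)
    Y = dataset.fluorescence if hasattr(dataset, "fluorescence") else np.asarray(dataset)
    q = Y.shape[1]
    if any(p < 1 or p >= q for p in p_grid):
        raise ValueError("p_grid must lie within [1, q-1]")
    if len(p_grid) == 1:
        return p_grid[0], {p_grid[0]: None}
    lls = {p: _cv_loglik(Y, model_id, p, folds, fit_kwargs) for p in p_grid}
    best = max(p_grid, key=lambda p: lls[p])
    return best, lls
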