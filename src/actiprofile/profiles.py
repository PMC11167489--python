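"""Latent profile analysis of ILR-transformed activity compositions.

A latent activity profile model is a finite mixture of diagonal
Gaussians on the three ILR balance coordinates, fitted by
expectation-maximization. The module provides the fit itself
(:func:`fit_mixture`), the usual fit statistics (AIC, BIC, normalized
entropy, smallest-class size), a parametric bootstrapped likelihood-ratio
test for K vs K−1 classes (:func:`blrt`), and the model-selection
protocol (:func:`select_profiles`): scan K, require the class-size rule
and a significant BLRT, then pick the lowest BIC.

Variance structures: ``"equal"`` (one diagonal covariance shared by all
classes — the simplest common LPA model, the default) and ``"free"``
(one diagonal covariance per class).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .composition import DEFAULT_SBP, ilr_inverse

_LOG2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Raised when every EM restart degenerates."""


@dataclass(frozen=True)
class MixtureConfig:
    """EM settings for one latent-profile fit."""

    variance_structure: str = "equal"  # "equal" or "free" diagonal
    n_restarts: int = 8
    max_iter: int = 500
    tol: float = 1e-7  # relative log-likelihood change
    variance_floor_frac: float = 1e-6
    kmeans_init: bool = True  # k-means start for restart 0 (random otherwise)
    seed: int = 0

    def __post_init__(self):
        if self.variance_structure not in ("equal", "free"):
            raise ValueError("variance_structure must be 'equal' or 'free'")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class ProfileSolution:
    """A fitted K-class mixture on n×d ILR data."""

    K: int
    means: np.ndarray  # (K, d)
    variances: np.ndarray  # (K, d); rows identical under "equal"
    weights: np.ndarray  # (K,)
    log_likelihood: float
    posteriors: np.ndarray  # (n, K)
    assignments: np.ndarray  # (n,) modal classes
    n_parameters: int
    converged: bool
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.K)


@dataclass
class FitStats:
    """Model-selection statistics for one fitted solution."""

    K: int
    aic: float
    bic: float
    entropy: float
    min_class_n: int
    min_class_frac: float
    blrt_p: float | None = None


def _n_parameters(K: int, d: int, structure: str) -> int:
    if structure == "equal":
        return K * d + d + (K - 1)
    return K * d + K * d + (K - 1)


def _log_gauss_diag(X, means, variances):
    # (n, K) log densities for diagonal Gaussians
    diff2 = (X[:, None, :] - means[None, :, :]) ** 2
    return -0.5 * (
        (diff2 / variances[None, :, :]).sum(axis=2)
        + np.log(variances).sum(axis=1)[None, :]
        + X.shape[1] * _LOG2PI
    )


def _em_once(X, K, config, rng, means0, max_iter=None):
    n, d = X.shape
    floor = config.variance_floor_frac * X.var(axis=0)
    means = means0.copy()
    if config.variance_structure == "equal":
        variances = np.tile(X.var(axis=0), (K, 1))
    else:
        variances = np.tile(X.var(axis=0), (K, 1))
    weights = np.full(K, 1.0 / K)
    ll_prev = -np.inf
    trace = []
    max_iter = config.max_iter if max_iter is None else max_iter
    for _ in range(max_iter):
        logp = _log_gauss_diag(X, means, variances) + np.log(weights)[None, :]
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(logp - norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise FitError("empty class during EM")
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        diff2 = (X[:, None, :] - means[None, :, :]) ** 2
        if config.variance_structure == "equal":
            v = (resp[:, :, None] * diff2).sum(axis=(0, 1)) / n
            variances = np.tile(np.maximum(v, floor), (K, 1))
        else:
            v = (resp[:, :, None] * diff2).sum(axis=0) / nk[:, None]
            variances = np.maximum(v, floor)
        if ll - ll_prev < config.tol * max(1.0, abs(ll)) and np.isfinite(ll_prev):
            ll_prev = ll
            break
        ll_prev = ll
    # final E-step consistent with returned parameters
    logp = _log_gauss_diag(X, means, variances) + np.log(weights)[None, :]
    norm = logsumexp(logp, axis=1)
    resp = np.exp(logp - norm[:, None])
    ll = float(norm.sum())
    trace.append(ll)
    return ProfileSolution(
        K=K,
        means=means,
        variances=variances,
        weights=weights,
        log_likelihood=ll,
        posteriors=resp,
        assignments=resp.argmax(axis=1),
        n_parameters=_n_parameters(K, d, config.variance_structure),
        converged=len(trace) < max_iter + 1,
        ll_trace=np.asarray(trace),
    )


def fit_mixture(
    X,
    K: int,
    config: MixtureConfig = MixtureConfig(),
    n_restarts: int | None = None,
    max_iter: int | None = None,
) -> ProfileSolution:
    """EM fit of a K-class diagonal-Gaussian mixture; best of all restarts.

    Restart 0 initializes from k-means centers; the remaining restarts
    draw random observations as initial means. The per-iteration
    log-likelihood is nondecreasing; convergence is declared when its
    relative change drops below ``config.tol``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n observations x d coordinates)")
    n, d = X.shape
    if n <= K:
        raise ValueError(f"need more observations than classes (n={n}, K={K})")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains missing or non-finite values")

    if K == 1:
        # closed-form single-component MLE
        means = X.mean(axis=0, keepdims=True)
        variances = X.var(axis=0, keepdims=True)
        logp = _log_gauss_diag(X, means, variances)
        ll = float(logp.sum())
        return ProfileSolution(
            K=1,
            means=means,
            variances=variances,
            weights=np.ones(1),
            log_likelihood=ll,
            posteriors=np.ones((n, 1)),
            assignments=np.zeros(n, dtype=int),
            n_parameters=_n_parameters(1, d, config.variance_structure),
            converged=True,
            ll_trace=np.array([ll]),
        )

    rng = np.random.default_rng(config.seed)
    restarts = config.n_restarts if n_restarts is None else n_restarts
    best = None
    for r in range(max(1, restarts)):
        try:
            if r == 0 and config.kmeans_init:
                km = KMeans(n_clusters=K, n_init=4, random_state=int(rng.integers(2**31)))
                labels = km.fit_predict(X)
                means0 = km.cluster_centers_
                if np.bincount(labels, minlength=K).min() == 0:
                    means0 = X[rng.choice(n, K, replace=False)]
            else:
                means0 = X[rng.choice(n, K, replace=False)]
            sol = _em_once(X, K, config, rng, means0, max_iter=max_iter)
        except FitError:
            continue
        if best is None or sol.log_likelihood > best.log_likelihood:
            best = sol
    if best is None:
        raise FitError(f"all EM restarts degenerated for K={K}")
    return best


def fit_statistics(solution: ProfileSolution, X) -> FitStats:
    """AIC, BIC, normalized entropy and smallest-class size for a fit.

    entropy = 1 − Σ_ik −p_ik ln p_ik / (n ln K): 1 for perfectly crisp
    posteriors, 0 for uniform ones; defined as 1 when K = 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ll = solution.log_likelihood
    p = solution.n_parameters
    aic = -2.0 * ll + 2.0 * p
    bic = -2.0 * ll + p * np.log(n)
    if solution.K == 1:
        entropy = 1.0
    else:
        post = np.clip(solution.posteriors, 1e-300, 1.0)
        ent = -(post * np.log(post)).sum()
        entropy = 1.0 - ent / (n * np.log(solution.K))
    counts = solution.class_counts
    return FitStats(
        K=solution.K,
        aic=float(aic),
        bic=float(bic),
        entropy=float(entropy),
        min_class_n=int(counts.min()),
        min_class_frac=float(counts.min() / n),
    )


def _simulate_from(solution: ProfileSolution, n: int, rng) -> np.ndarray:
    ks = rng.choice(solution.K, size=n, p=solution.weights)
    z = rng.standard_normal((n, solution.means.shape[1]))
    return solution.means[ks] + z * np.sqrt(solution.variances[ks])


def blrt(
    X,
    K: int,
    config: MixtureConfig = MixtureConfig(),
    B: int = 100,
    inner_restarts: int = 3,
    seed: int | None = None,
    lr_tol: float = 1e-5,
) -> float:
    """Parametric bootstrapped likelihood-ratio test of K vs K−1 classes.

    Observed LR = 2(ll_K − ll_{K−1}); B datasets are simulated from the
    fitted (K−1)-class model and refitted under both hypotheses (with
    ``inner_restarts`` restarts for speed). p = (1 + #{LR_b ≥ LR_obs}) /
    (B + 1), hence always in (0, 1]. Failed bootstrap fits are redrawn up
    to 3 times, then dropped with a warning. All fits inside the test —
    observed and bootstrap alike — use the same relative-log-likelihood
    tolerance ``lr_tol`` (looser than a final fit needs, since only the
    LR difference matters).
    """
    if K < 2:
        raise ValueError("BLRT requires K >= 2")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    config = replace(config, tol=max(config.tol, lr_tol))
    null_fit = fit_mixture(X, K - 1, config)
    alt_fit = fit_mixture(X, K, config)
    lr_obs = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)

    rng = np.random.default_rng(config.seed + 7919 * K if seed is None else seed)
    exceed = 0
    kept = 0
    for _ in range(B):
        lr_b = None
        for _retry in range(4):
            Xb = _simulate_from(null_fit, n, rng)
            try:
                cfg_b = replace(config, seed=int(rng.integers(2**31)), kmeans_init=False)
                ll0 = fit_mixture(Xb, K - 1, cfg_b, n_restarts=inner_restarts).log_likelihood
                ll1 = fit_mixture(Xb, K, cfg_b, n_restarts=inner_restarts).log_likelihood
                lr_b = 2.0 * (ll1 - ll0)
                break
            except FitError:
                continue
        if lr_b is None:
            import warnings

            warnings.warn("BLRT bootstrap replicate dropped after repeated fit failures")
            continue
        kept += 1
        if lr_b >= lr_obs:
            exceed += 1
    return (1 + exceed) / (kept + 1)


def select_profiles(
    X,
    K_range=range(1, 7),
    config: MixtureConfig = MixtureConfig(),
    B: int = 100,
    min_class_n: int = 25,
    min_class_frac: float | None = None,
    alpha: float = 0.05,
    inner_restarts: int = 3,
):
    """Scan K, build the fit table, and apply the selection protocol.

    A class count K is *eligible* when every class keeps at least
    ``min_class_n`` members (or, if ``min_class_frac`` is given instead,
    that fraction of n) under modal assignment, and — for K ≥ 2 — the
    BLRT against K−1 is significant at ``alpha``. Among eligible K the
    lowest BIC wins; ties break toward smaller K. If nothing is eligible
    the best-BIC solution is returned flagged "no model met criteria".

    Returns ``(solution, fit_table, note)`` where ``fit_table`` is a
    DataFrame with one row per K (AIC, BIC, entropy, BLRT-p, min class).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be nonempty")
    solutions, rows = {}, []
    for K in K_range:
        sol = fit_mixture(X, K, config)
        stats = fit_statistics(sol, X)
        if K >= 2:
            stats.blrt_p = blrt(X, K, config, B=B, inner_restarts=inner_restarts)
        solutions[K] = sol
        rows.append(stats)

    def eligible(st: FitStats) -> bool:
        if min_class_frac is not None:
            if st.min_class_frac <= min_class_frac:
                return False
        elif st.min_class_n < min_class_n:
            return False
        if st.K >= 2 and not (st.blrt_p is not None and st.blrt_p < alpha):
            return False
        return True

    table = pd.DataFrame(
        {
            "K": [s.K for s in rows],
            "AIC": [s.aic for s in rows],
            "BIC": [s.bic for s in rows],
            "entropy": [s.entropy for s in rows],
            "BLRT_p": [s.blrt_p for s in rows],
            "min_class_n": [s.min_class_n for s in rows],
            "min_class_frac": [s.min_class_frac for s in rows],
            "eligible": [eligible(s) for s in rows],
        }
    )
    elig = table[table["eligible"]]
    if len(elig):
        pick = elig.sort_values(["BIC", "K"]).iloc[0]
        note = ""
    else:
        pick = table.sort_values(["BIC", "K"]).iloc[0]
        note = "no model met criteria"
    return solutions[int(pick["K"])], table, note


def describe_profiles(
    solution: ProfileSolution,
    kappa: float = 100.0,
    sbp=DEFAULT_SBP,
    reference_ilr=None,
    tol: float = 0.5,
) -> pd.DataFrame:
    """Per-class compositional means (%/day) with above/below-mean labels.

    Class ILR means map back through the inverse ILR; each behavior is
    labeled "above", "below" or "average" relative to the whole-sample
    compositional mean (the weight-averaged class means unless a
    reference ILR vector is given). ``tol`` is the labeling dead band in
    the units of ``kappa`` (percentage points by default). Labels do not
    depend on the choice of kappa.
    """
    if reference_ilr is None:
        reference_ilr = (solution.weights[:, None] * solution.means).sum(axis=0)
    ref = ilr_inverse(np.asarray(reference_ilr, dtype=float), sbp, kappa)
    comps = ilr_inverse(solution.means, sbp, kappa)
    rows = []
    tol_scaled = tol * kappa / 100.0
    for k in range(solution.K):
        row = {"profile": k + 1, "n": int(solution.class_counts[k]),
               "weight": float(solution.weights[k])}
        for j, part in enumerate(("sleep", "sb", "lpa", "mvpa")):
            row[part] = float(comps[k, j])
            delta = comps[k, j] - ref[j]
            row[f"{part}_label"] = (
                "average" if abs(delta) <= tol_scaled else ("above" if delta > 0 else "below")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def match_classes(true_labels, pred_labels) -> np.ndarray:
    """Relabel predicted classes to best match true ones (Hungarian).

    Returns the permuted prediction; recovery metrics computed on it are
    invariant to label switching.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    kt = int(true_labels.max()) + 1
    kp = int(pred_labels.max()) + 1
    k = max(kt, kp)
    cost = np.zeros((k, k))
    for t in range(k):
        for p in range(k):
            cost[t, p] = -np.sum((true_labels == t) & (pred_labels == p))
    _, col = linear_sum_assignment(cost)
    mapping = np.empty(k, dtype=int)
    for t, p in enumerate(col):
        mapping[p] = t
    return mapping[pred_labels]
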