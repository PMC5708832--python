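"""Age-class decomposition of length-frequency samples.

October fork-length samples are modelled as a mixture of K univariate
normal distributions, one per age class; K (1..4) is chosen by BIC.  The
component with the smallest mean is interpreted as young-of-the-year
(YOY), the next as age 1, and so on.  Fitting is plain EM on 1-D data with
quantile-based k-means initialization, seeded multi-restarts, and a 1 mm
floor on component standard deviations (fork length is measured to the
millimetre, so narrower components are artefacts).

The EM is implemented here rather than delegated because downstream
checks need the per-iteration log-likelihood trace and the exact BIC
parameter count p = 3K - 1 (K means, K sds, K-1 free weights); an
independent library fit is used as a cross-check in the test-suite only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LengthSample",
    "MixtureFit",
    "InsufficientSampleError",
    "fit_mixture",
    "select_age_model",
    "yoy_summary",
]

VAR_FLOOR_SD = 1.0  # mm
_LOG_2PI = math.log(2.0 * math.pi)


class InsufficientSampleError(ValueError):
    """Raised when a sample is too small to identify K components (n < 3K)."""


@dataclass
class LengthSample:
    """Individual fork lengths for one site-year, optionally with pass labels."""

    site: str
    year: int
    lengths_mm: np.ndarray
    pass_labels: np.ndarray | None = None

    def __post_init__(self):
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        if self.lengths_mm.ndim != 1 or self.lengths_mm.size < 1:
            raise ValueError("lengths_mm must be a non-empty 1-D array")
        if np.any(self.lengths_mm <= 0):
            raise ValueError("all lengths must be positive")
        if self.pass_labels is not None:
            self.pass_labels = np.asarray(self.pass_labels)
            if self.pass_labels.shape != self.lengths_mm.shape:
                raise ValueError("pass_labels must align with lengths_mm")

    @property
    def n(self) -> int:
        return self.lengths_mm.size


@dataclass
class MixtureFit:
    """Fitted K-component normal mixture, components sorted by ascending mean."""

    K: int
    alpha: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    log_likelihood: float
    bic: float
    assignments: np.ndarray  # hard (max-posterior) component per fish
    responsibilities: np.ndarray  # (n, K) posterior membership
    ll_trace: np.ndarray  # per-iteration log-likelihood of the winning restart
    converged: bool
    variance_floored: bool
    yoy_index: int = 0
    bic_by_k: dict = field(default_factory=dict)


def _log_pdf_matrix(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (x[:, None] - mu[None, :]) / sigma[None, :]
    return -0.5 * (z**2 + _LOG_2PI) - np.log(sigma)[None, :]


def _em_once(x, alpha, mu, sigma, tol, max_iter, var_floor):
    """Run EM from one start; returns params, LL trace and flags."""
    n = x.size
    trace = []
    floored = False
    prev = -np.inf
    for _ in range(max_iter):
        # E step
        log_w = _log_pdf_matrix(x, mu, sigma) + np.log(alpha)[None, :]
        m = log_w.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_w - m).sum(axis=1))
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_w - log_norm[:, None])
        if ll - prev < tol and np.isfinite(prev):
            return alpha, mu, sigma, resp, np.array(trace), True, floored
        prev = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        alpha = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(var)
        if np.any(sigma < var_floor):
            floored = True
            sigma = np.maximum(sigma, var_floor)
    return alpha, mu, sigma, resp, np.array(trace), False, floored


def _init_params(x, K, rng, jitter):
    """Quantile-seeded 1-D k-means initialization (with optional jitter)."""
    qs = (np.arange(K) + 0.5) / K
    centers = np.quantile(x, qs)
    if jitter:
        centers = centers + rng.normal(0.0, max(x.std(), 1.0) / K, size=K)
    centers = np.sort(centers)
    for _ in range(25):  # Lloyd iterations on 1-D data
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [x[labels == k].mean() if np.any(labels == k) else centers[k] for k in range(K)]
        )
        if np.allclose(new, centers):
            break
        centers = np.sort(new)
    labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    alpha = np.array([max((labels == k).mean(), 1.0 / (10 * K)) for k in range(K)])
    alpha = alpha / alpha.sum()
    sigma = np.array(
        [
            x[labels == k].std() if np.sum(labels == k) > 1 else x.std() / K
            for k in range(K)
        ]
    )
    sigma = np.maximum(sigma, VAR_FLOOR_SD)
    return alpha, centers, sigma


def fit_mixture(
    sample: LengthSample,
    K: int,
    *,
    seed: int = 0,
    n_restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor: float = VAR_FLOOR_SD,
) -> MixtureFit:
    """Maximum-likelihood K-component normal mixture via EM.

    Deterministic for a given seed: restarts jitter the quantile k-means
    initialization with a seeded RNG and the best final log-likelihood wins.
    The per-iteration log-likelihood of the winning restart is recorded (EM
    guarantees it is non-decreasing).

    Raises
    ------
    InsufficientSampleError
        If n < 3K (identifiability floor).
    """
    if not 1 <= K:
        raise ValueError("K must be >= 1")
    x = sample.lengths_mm
    n = x.size
    if n < 3 * K:
        raise InsufficientSampleError(
            f"insufficient sample for K={K}: n={n} < {3 * K}"
        )
    rng = np.random.default_rng(seed)
    best = None
    n_starts = 1 if K == 1 else n_restarts
    for r in range(n_starts):
        alpha0, mu0, sigma0 = _init_params(x, K, rng, jitter=(r > 0))
        out = _em_once(x, alpha0, mu0, sigma0, tol, max_iter, var_floor)
        ll = out[4][-1]
        if best is None or ll > best[4][-1] + 1e-12:
            best = out
    alpha, mu, sigma, resp, trace, converged, floored = best
    order = np.argsort(mu)
    alpha, mu, sigma, resp = alpha[order], mu[order], sigma[order], resp[:, order]
    ll = float(trace[-1])
    p = 3 * K - 1
    bic = -2.0 * ll + p * math.log(n)
    return MixtureFit(
        K=K,
        alpha=alpha,
        mu=mu,
        sigma=sigma,
        log_likelihood=ll,
        bic=bic,
        assignments=np.argmax(resp, axis=1),
        responsibilities=resp,
        ll_trace=trace,
        converged=bool(converged),
        variance_floored=bool(floored),
    )


def select_age_model(sample: LengthSample, k_max: int = 4, **fit_kwargs) -> MixtureFit:
    """Exhaustively fit K = 1..k_max and return the fit minimizing BIC.

    K values infeasible for the sample size (n < 3K) are skipped; BIC ties
    break toward the smaller K (parsimony).  The BIC of every candidate is
    kept on the returned fit (``bic_by_k``).
    """
    best: MixtureFit | None = None
    bics: dict[int, float] = {}
    for K in range(1, k_max + 1):
        try:
            fit = fit_mixture(sample, K, **fit_kwargs)
        except InsufficientSampleError:
            continue
        bics[K] = fit.bic
        if best is None or fit.bic < best.bic - 1e-9:  # strict: ties keep smaller K
            best = fit
    if best is None:
        raise InsufficientSampleError(
            f"sample of n={sample.n} cannot support any K in 1..{k_max}"
        )
    best.bic_by_k = bics
    return best


def yoy_summary(fit: MixtureFit, sample: LengthSample):
    """Count, mean, sd and fraction of the YOY (smallest-mean) component.

    Counts use hard max-posterior assignments; uncaptured fish are assumed
    to follow the same mixture, so the fraction applies unchanged to the
    depletion-corrected abundance.  Returns
    ``(yoy_count, yoy_mean_mm, yoy_sd_mm, yoy_fraction)``.
    """
    idx = fit.yoy_index
    mask = fit.assignments == idx
    count = int(mask.sum())
    if count > 0:
        mean = float(sample.lengths_mm[mask].mean())
        sd = float(sample.lengths_mm[mask].std(ddof=1)) if count > 1 else 0.0
    else:  # fall back to the fitted component parameters
        mean, sd = float(fit.mu[idx]), float(fit.sigma[idx])
    return count, mean, sd, count / sample.n
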