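"""Information-theoretic model comparison: AICc, Akaike weights, evidence ratios.

All fitting modules funnel their residual sums of squares through this module
so that ranking tables share one arithmetic. AICc is the small-sample
corrected Akaike criterion; for least-squares fits with Gaussian errors it is
computed directly from the RSS, with the residual variance counted as a free
parameter (so a two-coefficient regression has k = 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelScore",
    "aicc_from_rss",
    "gaussian_log_likelihood",
    "score_from_rss",
    "delta_weights_evidence",
    "support_category",
    "summed_weight",
    "comparison_table",
]

#: interpretation bands for delta-AICc
SUPPORT_SUBSTANTIAL = "substantial"
SUPPORT_INTERMEDIATE = "intermediate"
SUPPORT_CONSIDERABLY_LESS = "considerably_less"
SUPPORT_ESSENTIALLY_NONE = "essentially_none"


@dataclass
class ModelScore:
    """Score card for one candidate model.

    Parameters
    ----------
    name : str
        Model label used in ranking tables.
    n : int
        Number of observations the model was fitted to.
    k : int
        Number of estimated parameters, *including* the residual variance
        for least-squares fits.
    rss : float, optional
        Residual sum of squares (least-squares fits).
    log_likelihood : float, optional
        Maximized log-likelihood (constant-inclusive Gaussian form when
        derived from an RSS).
    """

    name: str
    n: int
    k: int
    rss: float | None = None
    log_likelihood: float | None = None
    aicc: float | None = None
    delta: float | None = None
    weight: float | None = None
    evidence_ratio_against: float | None = None
    support: str | None = None
    extra: dict = field(default_factory=dict)


def aicc_from_rss(rss: float, n: int, k: int) -> float:
    """AICc for a Gaussian least-squares fit, from its residual sum of squares.

    ``aicc = n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1)``; additive constants that are
    common to all models fitted to the same data are omitted, so only
    differences are meaningful.

    Raises
    ------
    ValueError
        If ``n <= k + 1`` (the small-sample correction is undefined) or
        ``rss <= 0``.
    """
    if rss <= 0:
        raise ValueError(f"rss must be positive, got {rss}")
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n}, k={k}: requires n > k + 1"
        )
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def gaussian_log_likelihood(rss: float, n: int) -> float:
    """Constant-inclusive Gaussian log-likelihood at the MLE variance rss/n."""
    if rss <= 0 or n <= 0:
        raise ValueError("rss and n must be positive")
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)


def score_from_rss(name: str, rss: float, n: int, k: int) -> ModelScore:
    """Build a :class:`ModelScore` from a least-squares fit."""
    return ModelScore(
        name=name,
        n=n,
        k=k,
        rss=rss,
        log_likelihood=gaussian_log_likelihood(rss, n),
        aicc=aicc_from_rss(rss, n, k),
    )


def support_category(delta: float) -> str:
    """Interpretation band for a delta-AICc value.

    ``delta < 2`` counts as substantial support for the model despite not
    ranking first; ``delta > 4`` considerably less; ``delta > 10``
    essentially none; values in ``[2, 4]`` are labelled intermediate.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta < 2:
        return SUPPORT_SUBSTANTIAL
    if delta <= 4:
        return SUPPORT_INTERMEDIATE
    if delta <= 10:
        return SUPPORT_CONSIDERABLY_LESS
    return SUPPORT_ESSENTIALLY_NONE


def delta_weights_evidence(scores: list[ModelScore]) -> list[ModelScore]:
    """Fill delta, Akaike weight, evidence ratio and support for a model set.

    Returns the scores sorted by ascending AICc (rank order). Weights are
    ``exp(-delta_i/2)`` normalized over the set; the evidence ratio against
    model *i* is ``weight_top / weight_i`` (1 for the top model itself).
    """
    if len(scores) < 2:
        raise ValueError("need at least two models to compare")
    for s in scores:
        if s.aicc is None:
            raise ValueError(f"model {s.name!r} has no AICc")
    ranked = sorted(scores, key=lambda s: s.aicc)
    best = ranked[0].aicc
    rel = np.array([math.exp(-(s.aicc - best) / 2.0) for s in ranked])
    weights = rel / rel.sum()
    for s, w in zip(ranked, weights):
        s.delta = s.aicc - best
        s.weight = float(w)
        s.evidence_ratio_against = float(weights[0] / w)
        s.support = support_category(s.delta)
    return ranked


def summed_weight(scores: list[ModelScore], names: list[str]) -> tuple[float, float]:
    """Summed Akaike weight of a model subset and the implied odds w/(1-w)."""
    total = sum(s.weight for s in scores if s.name in set(names))
    if not 0 <= total <= 1 + 1e-9:
        raise ValueError("weights not normalized; run delta_weights_evidence first")
    odds = math.inf if total >= 1 else total / (1.0 - total)
    return total, odds


def comparison_table(scores: list[ModelScore]) -> pd.DataFrame:
    """Ranking table (Model, K, AICc, Delta, Wt, LL, Evidence Ratio Against)."""
    ranked = delta_weights_evidence(list(scores))
    return pd.DataFrame(
        {
            "Model": [s.name for s in ranked],
            "K": [s.k for s in ranked],
            "AICc": [s.aicc for s in ranked],
            "Delta": [s.delta for s in ranked],
            "Wt": [s.weight for s in ranked],
            "LL": [s.log_likelihood for s in ranked],
            "EvidenceRatioAgainst": [s.evidence_ratio_against for s in ranked],
            "Support": [s.support for s in ranked],
        }
    )
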