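"""Life-cycle models linking juvenile cohorts to returning adults.

Two competing predictors of the annual adult count are implemented.  The
fixed-rate model assumes every juvenile has the same probability of
smolting, surviving at sea and returning:

    A_t = q1*(0.53*J_{t-1} + 0.47*J_{t-2}) + q2*(0.53*C_{t-1} + 0.47*C_{t-2})

where J is wild young-of-the-year (YOY) abundance the previous October, C
is the number of captively reared juveniles released, and (0.53, 0.47) is
the fixed split of adults returning after one versus two years at sea.
The size-conditional model replaces J and C by "smolt-equivalents" J*, C*:
abundance weighted by each fish's product of a logistic smolting
probability (threshold 120 mm, dispersion 10 mm on 1 April length) and a
size-dependent early marine survival curve truncated at 0.35.

The apparent transition rates q are fitted by ordinary least squares with
no intercept and no sign constraint; they confound true vital rates with
the fixed sampling biases of the monitoring series, and are interpreted
accordingly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SmoltParams",
    "SurvivalParams",
    "CohortInputs",
    "TransitionFit",
    "OCEAN_AGE_SPLIT",
    "smolt_probability",
    "marine_survival",
    "cap_binding_length",
    "smolt_equivalents",
    "lagged_predictor",
    "predict_adults",
    "fit_transition_rates",
    "decompose_origin",
]

#: proportion of adults returning after 1 vs 2 years at sea
OCEAN_AGE_SPLIT = (0.53, 0.47)

FIXED_RATE = "fixed_rate"
SIZE_CONDITIONAL = "size_conditional"


@dataclass(frozen=True)
class SmoltParams:
    """Logistic smolting curve: threshold (inflection) length and dispersion."""

    L_s: float = 120.0
    sigma_s: float = 10.0

    def __post_init__(self):
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")


@dataclass(frozen=True)
class SurvivalParams:
    """Truncated logistic early-marine-survival curve.

    s(L) = min(ceiling, asymptote / (1 + exp(intercept - slope*L))).
    """

    ceiling: float = 0.35
    asymptote: float = 0.84
    intercept: float = 8.657
    slope: float = 0.0369  # per mm

    def __post_init__(self):
        if not (0 < self.ceiling):
            raise ValueError("ceiling must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


def smolt_probability(length_mm, params: SmoltParams = SmoltParams()):
    """Probability that a juvenile of given 1-April length smolts.

    Logistic in length, 0.5 at the threshold, strictly increasing.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    return 1.0 / (1.0 + np.exp(-(length_mm - params.L_s) / params.sigma_s))


def marine_survival(length_mm, params: SurvivalParams = SurvivalParams()):
    """Early marine survival as a function of length at ocean entry (mm)."""
    length_mm = np.asarray(length_mm, dtype=float)
    logistic = params.asymptote / (
        1.0 + np.exp(params.intercept - params.slope * length_mm)
    )
    return np.minimum(params.ceiling, logistic)


def cap_binding_length(params: SurvivalParams = SurvivalParams()) -> int:
    """Smallest whole-mm length at which the survival ceiling binds.

    Closed form: ceil((intercept - ln(asymptote/ceiling - 1)) / slope).

    Raises
    ------
    ValueError
        If the ceiling is at or above the asymptote (never binds).
    """
    if params.ceiling >= params.asymptote:
        raise ValueError("ceiling >= asymptote: truncation never binds")
    exact = (params.intercept - math.log(params.asymptote / params.ceiling - 1.0)) / params.slope
    return int(math.ceil(exact - 1e-12))


def smolt_equivalents(
    april_lengths_mm,
    total_abundance: float,
    smolt_params: SmoltParams = SmoltParams(),
    survival_params: SurvivalParams = SurvivalParams(),
) -> float:
    """Smolt-equivalent abundance J* (or C*) for a cohort.

    The mean over fish of smolting probability times marine survival,
    scaled by the cohort's total abundance.
    """
    if total_abundance < 0:
        raise ValueError("abundance must be non-negative")
    if total_abundance == 0:
        return 0.0
    lengths = np.asarray(april_lengths_mm, dtype=float)
    if lengths.size == 0:
        raise ValueError("no lengths supplied for a cohort with positive abundance")
    per_fish = smolt_probability(lengths, smolt_params) * marine_survival(
        lengths, survival_params
    )
    return float(per_fish.mean() * total_abundance)


@dataclass
class CohortInputs:
    """Aligned annual series feeding the life-cycle regressions.

    All arrays share the index of ``years``; NaN marks a missing year.
    ``wild``/``captive`` are the raw predictors (J_t, C_t); the starred
    versions are smolt-equivalents.
    """

    years: np.ndarray
    adults: np.ndarray
    wild: np.ndarray
    captive: np.ndarray
    wild_star: np.ndarray | None = None
    captive_star: np.ndarray | None = None
    ocean_age_split: tuple[float, float] = OCEAN_AGE_SPLIT

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        for name in ("adults", "wild", "captive", "wild_star", "captive_star"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.years.shape:
                    raise ValueError(f"{name} not aligned with years")
                setattr(self, name, v)
        if abs(sum(self.ocean_age_split) - 1.0) > 1e-9:
            raise ValueError("ocean_age_split must sum to 1")

    def predictors(self, model: str) -> tuple[np.ndarray, np.ndarray]:
        if model == FIXED_RATE:
            return self.wild, self.captive
        if model == SIZE_CONDITIONAL:
            if self.wild_star is None or self.captive_star is None:
                raise ValueError("smolt-equivalents missing for size-conditional model")
            return self.wild_star, self.captive_star
        raise ValueError(f"unknown model {model!r}")


def lagged_predictor(series: np.ndarray, split: tuple[float, float] = OCEAN_AGE_SPLIT) -> np.ndarray:
    """Ocean-age weighted lag combination 0.53*x_{t-1} + 0.47*x_{t-2}.

    The first two positions (no lags available) and any position whose lag
    is NaN come back as NaN.
    """
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    if x.size >= 3:
        out[2:] = split[0] * x[1:-1] + split[1] * x[:-2]
    return out


@dataclass
class TransitionFit:
    """Least-squares fit of the apparent transition rates for one model."""

    model: str
    q: np.ndarray  # (q_wild, q_captive); NaN if the coefficient was dropped
    se: np.ndarray
    rss: float
    n_years: int
    years: np.ndarray  # years actually used
    predictions: np.ndarray  # aligned to `years`
    observed: np.ndarray
    wild_term: np.ndarray  # lagged predictor columns, aligned to `years`
    captive_term: np.ndarray
    dropped: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return int(np.sum(~np.isnan(self.q)))


def predict_adults(inputs: CohortInputs, q, model: str):
    """Predicted adult series under a model at given transition rates.

    Returns ``(years, predictions)`` restricted to years where both lagged
    predictors exist. Linear in q by construction.
    """
    wild, captive = inputs.predictors(model)
    xw = lagged_predictor(wild, inputs.ocean_age_split)
    xc = lagged_predictor(captive, inputs.ocean_age_split)
    usable = ~(np.isnan(xw) | np.isnan(xc))
    q = np.asarray(q, dtype=float)
    pred = q[0] * xw[usable] + q[1] * xc[usable]
    return inputs.years[usable], pred


def fit_transition_rates(
    inputs: CohortInputs,
    model: str,
    exclude_years: tuple[int, ...] = (),
) -> TransitionFit:
    """Fit (q_wild, q_captive) by OLS with no intercept.

    The regression has no intercept because the life-cycle equations have
    none; coefficients are unconstrained in sign.  Years lacking either lag,
    with a missing adult count, or listed in ``exclude_years`` are dropped.
    An all-zero (or otherwise degenerate) predictor column is dropped from
    the design with a flag rather than producing a singular solve.
    """
    wild, captive = inputs.predictors(model)
    xw = lagged_predictor(wild, inputs.ocean_age_split)
    xc = lagged_predictor(captive, inputs.ocean_age_split)
    usable = ~(np.isnan(xw) | np.isnan(xc) | np.isnan(inputs.adults))
    usable &= ~np.isin(inputs.years, list(exclude_years))
    years = inputs.years[usable]
    y = inputs.adults[usable]
    X = np.column_stack([xw[usable], xc[usable]])
    n = len(y)
    if n < 4:
        raise ValueError(f"need >= 4 usable years, have {n}")

    cols = [0, 1]
    dropped: list[str] = []
    norms = np.linalg.norm(X, axis=0)
    for j, label in enumerate(("wild", "captive")):
        if norms[j] == 0:
            cols.remove(j)
            dropped.append(label)
            warnings.warn(f"degenerate {label} predictor dropped from {model} design")
    Xu = X[:, cols]
    beta, _, rank, _ = np.linalg.lstsq(Xu, y, rcond=None)
    resid = y - Xu @ beta
    rss = float(resid @ resid)
    dof = n - len(cols)
    sigma2 = rss / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(Xu.T @ Xu)
    q = np.full(2, np.nan)
    se = np.full(2, np.nan)
    q[cols] = beta
    se[cols] = np.sqrt(np.diag(cov))
    pred = Xu @ beta
    return TransitionFit(
        model=model,
        q=q,
        se=se,
        rss=rss,
        n_years=n,
        years=years,
        predictions=pred,
        observed=y,
        wild_term=X[:, 0],
        captive_term=X[:, 1],
        dropped=dropped,
    )


def decompose_origin(fit: TransitionFit):
    """Split each year's predicted adults into wild and captive origin.

    Returns ``(years, wild_pred, captive_pred)``; the two components sum to
    the total prediction exactly (the model is additive in origin).
    """
    qw = 0.0 if np.isnan(fit.q[0]) else fit.q[0]
    qc = 0.0 if np.isnan(fit.q[1]) else fit.q[1]
    wild_pred = qw * fit.wild_term
    captive_pred = qc * fit.captive_term
    return fit.years, wild_pred, captive_pred
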