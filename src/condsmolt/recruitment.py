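"""Density-regulation (recruitment) models and covariate regressions.

Six competing models for October young-of-the-year abundance J_t as a
function of adult spawners A_t and translocated juveniles R_t:

    fixed production                J = K
    proportional                    J = r*A
    logistic capacity               J = r*A*(1 - r*A/K)
    ... each optionally + s*R (a fraction s of translocated fish surviving
    to the October survey)

fitted by bounded nonlinear least squares and ranked by AICc (residual
variance counted as a parameter, so the fixed-production model has k = 2
and logistic capacity + translocations has k = 4).

Because the monitoring series carry known fixed sampling biases (adult
counts omit reaches holding 44.8% of accessible stream km; surveys omit
61.5%), fitted coefficients are "apparent" values; ``bias_correct``
applies the spatial-evenness correction arithmetic to recover the
underlying quantities.

A separate set of ordinary linear regressions relates October mean YOY
length to streamflow, spawner counts and translocations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .model_selection import ModelScore, delta_weights_evidence, score_from_rss

__all__ = [
    "RecruitmentModelSpec",
    "BiasConstants",
    "RECRUITMENT_MODELS",
    "LENGTH_MODEL_TERMS",
    "model_spec",
    "predict_recruitment",
    "fit_recruitment",
    "fit_all_recruitment",
    "bias_correct",
    "bias_restore",
    "expected_wild_transition",
    "transition_shortfall",
    "fit_length_models",
]

PARAM_BOUNDS = {"K": (1.0, 1e7), "r": (1e-6, 1e4), "s": (0.0, 10.0)}

RECRUITMENT_MODELS = (
    "fixed_production",
    "proportional",
    "logistic_capacity",
    "fixed_production_translocations",
    "proportional_translocations",
    "logistic_capacity_translocations",
)


@dataclass(frozen=True)
class RecruitmentModelSpec:
    """One candidate density-regulation model."""

    name: str
    params: tuple[str, ...]
    with_translocations: bool
    family: str  # fixed | proportional | logistic

    @property
    def k(self) -> int:
        """AICc parameter count: coefficients + residual variance."""
        return len(self.params) + 1


def model_spec(name: str) -> RecruitmentModelSpec:
    if name not in RECRUITMENT_MODELS:
        raise ValueError(f"unknown recruitment model {name!r}")
    with_r = name.endswith("_translocations")
    family = name.replace("_translocations", "")
    base_params = {
        "fixed_production": ("K",),
        "proportional": ("r",),
        "logistic_capacity": ("r", "K"),
    }[family]
    params = base_params + (("s",) if with_r else ())
    family_short = {"fixed_production": "fixed", "proportional": "proportional",
                    "logistic_capacity": "logistic"}[family]
    return RecruitmentModelSpec(name, params, with_r, family_short)


def predict_recruitment(spec: RecruitmentModelSpec, params: dict, A, R=None):
    """Expected October YOY abundance under a model.

    The logistic-capacity form can go negative when r*A > K; predictions
    are floored at 0 with a warning (the fitter treats such parameter
    vectors as simply fitting poorly).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("adult counts must be non-negative")
    if spec.family == "fixed":
        pred = np.full_like(A, float(params["K"]))
    elif spec.family == "proportional":
        pred = params["r"] * A
    else:
        rA = params["r"] * A
        pred = rA * (1.0 - rA / params["K"])
        if np.any(pred < 0):
            warnings.warn("logistic-capacity prediction below 0 floored")
            pred = np.maximum(pred, 0.0)
    if spec.with_translocations:
        if R is None:
            raise ValueError(f"{spec.name} needs the translocation series")
        R = np.asarray(R, dtype=float)
        if np.any(R < 0):
            raise ValueError("translocation counts must be non-negative")
        pred = pred + params["s"] * R
    return pred


def _start_grid(spec: RecruitmentModelSpec, J, A, R, n_starts: int, seed: int):
    """Log-spaced multi-start grid informed by the data scale."""
    rng = np.random.default_rng(seed)
    scale = {
        "K": max(np.mean(J), 1.0),
        "r": max(np.mean(J) / max(np.mean(A), 1.0), 1e-3),
        "s": 1.0,
    }
    starts = []
    for _ in range(n_starts):
        x0 = []
        for p in spec.params:
            lo, hi = PARAM_BOUNDS[p]
            v = scale[p] * 10 ** rng.uniform(-1.0, 1.0)
            x0.append(float(np.clip(v, lo, hi)))
        starts.append(x0)
    return starts


def fit_recruitment(
    name: str,
    J,
    A,
    R=None,
    *,
    n_starts: int = 16,
    seed: int = 0,
) -> tuple[dict, ModelScore]:
    """Bounded nonlinear least squares for one recruitment model.

    Returns the fitted parameter dict (with standard errors under
    ``'se'``) and a :class:`ModelScore` fed from the RSS with
    k = |params| + 1.  Non-convergence across all starts raises.
    """
    spec = model_spec(name)
    J = np.asarray(J, dtype=float)
    A = np.asarray(A, dtype=float)
    n = J.size
    if n < spec.k + 1:
        raise ValueError(f"{name}: need >= {spec.k + 1} years, have {n}")

    def resid(x):
        params = dict(zip(spec.params, x))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return predict_recruitment(spec, params, A, R) - J

    lo = [PARAM_BOUNDS[p][0] for p in spec.params]
    hi = [PARAM_BOUNDS[p][1] for p in spec.params]
    best = None
    for x0 in _start_grid(spec, J, A, R, n_starts, seed):
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(f"{name}: no start converged")
    params = dict(zip(spec.params, (float(v) for v in best.x)))
    rss = float(2.0 * best.cost)
    # asymptotic SEs from the Jacobian at the optimum
    dof = max(n - len(spec.params), 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(best.jac.T @ best.jac)
        se = dict(zip(spec.params, np.sqrt(np.diag(cov))))
    except np.linalg.LinAlgError:
        se = {p: float("nan") for p in spec.params}
    params["se"] = se
    score = score_from_rss(name, rss, n, spec.k)
    return params, score


def fit_all_recruitment(J, A, R, **kwargs):
    """Fit and rank all six models; returns (ranked scores, params by name).

    Models that fail to converge are excluded from the ranking with a
    warning rather than aborting the comparison.
    """
    scores, fitted = [], {}
    for name in RECRUITMENT_MODELS:
        try:
            params, score = fit_recruitment(name, J, A, R, **kwargs)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"{name} excluded from ranking: {exc}")
            continue
        fitted[name] = params
        scores.append(score)
    return delta_weights_evidence(scores), fitted


@dataclass(frozen=True)
class BiasConstants:
    """Fixed sampling biases of the monitoring series.

    ``adult_bias``: proportional bias of the ladder counts under spatially
    even spawning (-0.448).  ``juvenile_bias``: bias of the October survey
    expansion from unsurveyed reaches (-0.615).  ``correction_ratio`` is
    the printed divisor (1.41) applied to per-spawner production; note it
    differs slightly from the transition-rate ratio
    (1-adult_bias)/(1-juvenile_bias) = 1.43 -- both are kept and each is
    used exactly where the original analysis used it.
    """

    adult_bias: float = -0.448
    juvenile_bias: float = -0.615
    correction_ratio: float = 1.41

    def __post_init__(self):
        if not (-1 < self.adult_bias < 0 and -1 < self.juvenile_bias < 0):
            raise ValueError("biases must be in (-1, 0)")


def expected_wild_transition(constants: BiasConstants = BiasConstants()) -> float:
    """Wild apparent transition expected from biases alone.

    (1 + adult_bias) / (1 + juvenile_bias): the value q3 would take with
    negligible overwinter mortality and spatially even distributions.
    """
    return (1.0 + constants.adult_bias) / (1.0 + constants.juvenile_bias)


def transition_shortfall(
    estimate: float, constants: BiasConstants = BiasConstants()
) -> float:
    """Fractional shortfall of an estimated wild transition vs expectation."""
    return 1.0 - estimate / expected_wild_transition(constants)


def bias_correct(params: dict, constants: BiasConstants = BiasConstants()) -> dict:
    """Apply the spatial-evenness bias-correction arithmetic.

    r -> r / correction_ratio; K -> K / (1 + juvenile_bias);
    s -> s * (1 + juvenile_bias).  Parameters absent from the input pass
    through untouched; the expected wild transition is attached.
    """
    out = {}
    if "r" in params:
        out["r"] = params["r"] / constants.correction_ratio
    if "K" in params:
        out["K"] = params["K"] / (1.0 + constants.juvenile_bias)
    if "s" in params:
        out["s"] = params["s"] * (1.0 + constants.juvenile_bias)
    out["expected_wild_transition"] = expected_wild_transition(constants)
    return out


def bias_restore(corrected: dict, constants: BiasConstants = BiasConstants()) -> dict:
    """Inverse of :func:`bias_correct` (round-trip identity)."""
    out = {}
    if "r" in corrected:
        out["r"] = corrected["r"] * constants.correction_ratio
    if "K" in corrected:
        out["K"] = corrected["K"] * (1.0 + constants.juvenile_bias)
    if "s" in corrected:
        out["s"] = corrected["s"] / (1.0 + constants.juvenile_bias)
    return out


#: predictor combinations for the October YOY length regressions, in rank-table order
LENGTH_MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "flow": ("flow",),
    "adults_translocations": ("adults", "translocations"),
    "adults_flow": ("adults", "flow"),
    "translocations_flow": ("translocations", "flow"),
    "translocations": ("translocations",),
    "intercept_only": (),
    "adults": ("adults",),
}


def fit_length_models(data: pd.DataFrame):
    """OLS (with intercept) of mean October YOY length on covariates.

    ``data`` needs columns mean_length, adults, translocations, flow, one
    row per year.  All seven predictor combinations are fitted and ranked
    by AICc with k = coefficients (incl. intercept) + 1.  Returns
    ``(ranked ModelScores, {name: statsmodels results})``; strongly
    collinear designs are reported via the condition number on the score,
    never dropped.
    """
    required = {"mean_length", "adults", "translocations", "flow"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data missing columns: {sorted(missing)}")
    if len(data) < 6:
        raise ValueError("need at least 6 years for the length regressions")
    y = data["mean_length"].to_numpy(dtype=float)
    scores, fits = [], {}
    for name, terms in LENGTH_MODEL_TERMS.items():
        X = sm.add_constant(
            data.loc[:, list(terms)].to_numpy(dtype=float)
            if terms
            else np.empty((len(data), 0))
        )
        res = sm.OLS(y, X).fit()
        rss = float(res.ssr)
        k = X.shape[1] + 1
        score = score_from_rss(name, rss, len(y), k)
        score.extra["terms"] = terms
        score.extra["adj_r2"] = float(res.rsquared_adj) if terms else float("nan")
        score.extra["condition_number"] = float(np.linalg.cond(X))
        if score.extra["condition_number"] > 1e8:
            warnings.warn(f"{name}: ill-conditioned design")
        scores.append(score)
        fits[name] = res
    return delta_weights_evidence(scores), fits
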