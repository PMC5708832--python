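"""Removal (depletion) abundance estimation and river-wide expansion.

October electrofishing surveys make 2 or 3 sequential passes through a
closed site; under a constant per-pass capture probability the catch
declines geometrically and site abundance can be estimated from the decline
(Zippin's removal method for 3 passes, Seber-LeCren for 2).  Site YOY
densities (fish per longitudinal metre of channel) are then averaged across
sites and expanded by the channel length between the upper dam and the
estuary to an annual river-wide YOY abundance J_t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "DepletionCounts",
    "AbundanceEstimate",
    "zippin_three_pass",
    "seber_lecren_two_pass",
    "estimate_abundance",
    "annual_yoy_abundance",
]

ZIPPIN3 = "zippin3"
SEBER_LECREN2 = "seber_lecren2"
TOTAL_CATCH_FALLBACK = "total_catch_fallback"


@dataclass(frozen=True)
class DepletionCounts:
    """Ordered per-pass catches for one site-year."""

    site: str
    year: int
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) not in (2, 3):
            raise ValueError("2 or 3 passes required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


@dataclass
class AbundanceEstimate:
    """Estimated site abundance with the method that produced it."""

    n_hat: float
    p_hat: float  # NaN when undefined (fallback / empty site)
    method: str
    counts: tuple[int, ...]
    site: str | None = None
    year: int | None = None


def _removal_profile_negll(p: float, counts) -> float:
    """Negative continuous-N profile log-likelihood of the removal model.

    N is profiled out at N(p) = T / (1 - q^k); factorial terms use the
    Stirling form N ln N - (N-T) ln(N-T) - T, under which the maximizer
    reproduces the classical removal estimator exactly.
    """
    k = len(counts)
    T = sum(counts)
    q = 1.0 - p
    denom = 1.0 - q**k
    N = T / denom
    rem = N - T
    ll = N * np.log(N) - T
    if rem > 0:
        ll -= rem * np.log(rem)
    for i, c in enumerate(counts):
        if c > 0:
            ll += c * np.log(p * q**i)
    if rem > 0:
        ll += rem * k * np.log(q)
    return -ll


def zippin_three_pass(counts) -> AbundanceEstimate:
    """Constant-p removal MLE from three passes.

    Maximizes the profile likelihood over p in (0.01, 1); N is profiled out
    as T / (1 - (1-p)^3).  When the catches show no depletion signal (no
    interior maximum, i.e. sum((i-1)*c_i)/T >= 1 for 3 passes) the estimate
    falls back to the total catch with a method flag.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3:
        raise ValueError("zippin_three_pass requires exactly 3 passes")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    T = sum(counts)
    if T == 0:
        return AbundanceEstimate(0.0, float("nan"), ZIPPIN3, counts)
    k = 3
    # Zippin interior-maximum condition: mean removal index below (k-1)/2.
    R = sum(i * c for i, c in enumerate(counts)) / T
    if R >= (k - 1) / 2:
        return AbundanceEstimate(float(T), float("nan"), TOTAL_CATCH_FALLBACK, counts)
    if R == 0:  # exhausted on first pass
        return AbundanceEstimate(float(T), 1.0, ZIPPIN3, counts)
    res = minimize_scalar(
        _removal_profile_negll,
        args=(counts,),
        bounds=(0.01, 1.0 - 1e-9),
        method="bounded",
        options={"xatol": 1e-8},
    )
    p = float(res.x)
    if 1.0 - p < 1e-6:
        return AbundanceEstimate(float(T), 1.0, ZIPPIN3, counts)
    n_hat = T / (1.0 - (1.0 - p) ** k)
    return AbundanceEstimate(float(n_hat), p, ZIPPIN3, counts)


def seber_lecren_two_pass(counts) -> AbundanceEstimate:
    """Two-pass removal estimator: N = c1^2/(c1-c2), p = 1 - c2/c1.

    Undefined when c1 <= c2; falls back to the total catch with a flag.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 2:
        raise ValueError("seber_lecren_two_pass requires exactly 2 passes")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    c1, c2 = counts
    if c1 + c2 == 0:
        return AbundanceEstimate(0.0, float("nan"), SEBER_LECREN2, counts)
    if c1 <= c2:
        return AbundanceEstimate(float(c1 + c2), float("nan"), TOTAL_CATCH_FALLBACK, counts)
    n_hat = c1**2 / (c1 - c2)
    p_hat = 1.0 - c2 / c1
    return AbundanceEstimate(float(n_hat), float(p_hat), SEBER_LECREN2, counts)


def estimate_abundance(dc: DepletionCounts) -> AbundanceEstimate:
    """Dispatch on the number of passes."""
    if len(dc.counts) == 3:
        est = zippin_three_pass(dc.counts)
    else:
        est = seber_lecren_two_pass(dc.counts)
    est.site = dc.site
    est.year = dc.year
    return est


def annual_yoy_abundance(
    site_table: pd.DataFrame, channel_length_m: float
) -> pd.DataFrame:
    """Expand site YOY densities to an annual river-wide abundance J_t.

    ``site_table`` needs columns site, year, n_hat, yoy_fraction,
    site_length_m.  For each year, J_t = mean over surveyed sites of
    (n_hat * yoy_fraction / site_length_m) * channel_length_m.  Years with
    no usable sites are absent from the result; sites with missing
    estimates are excluded from the mean with a warning.
    """
    if channel_length_m <= 0:
        raise ValueError("channel_length_m must be positive")
    required = {"site", "year", "n_hat", "yoy_fraction", "site_length_m"}
    missing = required - set(site_table.columns)
    if missing:
        raise ValueError(f"site_table missing columns: {sorted(missing)}")
    df = site_table.copy()
    bad = df["n_hat"].isna() | df["yoy_fraction"].isna()
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} site-year(s) with missing estimates"
        )
        df = df[~bad]
    df["density_per_m"] = df["n_hat"] * df["yoy_fraction"] / df["site_length_m"]
    out = (
        df.groupby("year")
        .agg(mean_density=("density_per_m", "mean"), n_sites=("site", "nunique"))
        .reset_index()
    )
    out["J_t"] = out["mean_density"] * channel_length_m
    return out[["year", "J_t", "n_sites", "mean_density"]]
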