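"""End-to-end analysis pipeline over the monitoring tables.

Chains the stages: length-sample age decomposition -> depletion abundance
and river-wide expansion -> growth-parameter fitting and 1-April size
projection -> life-cycle model comparison (fixed-rate vs size-conditional)
-> recruitment and YOY-length model rankings.  Each stage is a plain
function over pandas DataFrames so drivers, tests and the CLI share one
code path; ``run_report`` executes the whole chain and writes the ranking
tables plus a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import age_structure as ages
from . import growth as gr
from . import lifecycle as lc
from . import model_selection as ms
from . import recruitment as rec
from .synthetic_data import (
    APRIL_FIRST_MONTH_DAY,
    OCTOBER_SURVEY_MONTH_DAY,
    SyntheticDataset,
)

__all__ = [
    "PipelineOptions",
    "run_ages",
    "run_abundance",
    "run_growth",
    "april_lengths_table",
    "build_cohort_inputs",
    "build_cohort_inputs_from_tables",
    "run_lifecycle",
    "run_recruitment",
    "run_length_models",
    "run_report",
]


@dataclass
class PipelineOptions:
    """Tuning knobs shared by all stages; defaults are full quality."""

    k_max: int = 4
    em_restarts: int = 20
    em_max_iter: int = 500
    em_seed: int = 0
    cohort_n: int = 200
    growth_starts: int = 8
    n_passes: int = 3
    channel_length_m: float = 40_000.0
    site_length_m: float = 100.0
    exclude_years: tuple[int, ...] = ()
    seed: int = 0

    @classmethod
    def fast(cls, **overrides) -> "PipelineOptions":
        """Reduced-cost preset for replicated end-to-end simulations.

        Smaller simulated cohorts, fewer optimizer multistarts and fewer EM
        restarts; estimator structure is unchanged.
        """
        opts = cls(em_restarts=3, em_max_iter=150, cohort_n=60, growth_starts=3)
        for k, v in overrides.items():
            setattr(opts, k, v)
        return opts


def run_ages(survey: pd.DataFrame, opts: PipelineOptions) -> pd.DataFrame:
    """Mixture age decomposition per site-year.

    Returns one row per site-year with the BIC-selected K, component
    parameters and the YOY summary used downstream.
    """
    rows = []
    for (site, year), grp in survey.groupby(["site", "year"], sort=True):
        sample = ages.LengthSample(
            site=str(site),
            year=int(year),
            lengths_mm=grp["length_mm"].to_numpy(),
            pass_labels=grp["pass"].to_numpy(),
        )
        try:
            fit = ages.select_age_model(
                sample,
                k_max=opts.k_max,
                seed=opts.em_seed,
                n_restarts=opts.em_restarts,
                max_iter=opts.em_max_iter,
            )
        except ages.InsufficientSampleError as exc:
            warnings.warn(f"{site} {year}: {exc}")
            continue
        count, mean, sd, frac = ages.yoy_summary(fit, sample)
        row = {
            "site": site,
            "year": int(year),
            "n": sample.n,
            "K": fit.K,
            "bic": fit.bic,
            "yoy_count": count,
            "yoy_mean": mean,
            "yoy_sd": sd,
            "yoy_fraction": frac,
        }
        for k in range(fit.K):
            row[f"alpha_{k + 1}"] = fit.alpha[k]
            row[f"mu_{k + 1}"] = fit.mu[k]
            row[f"sigma_{k + 1}"] = fit.sigma[k]
        rows.append(row)
    return pd.DataFrame(rows)


def run_abundance(
    survey: pd.DataFrame, ages_df: pd.DataFrame, opts: PipelineOptions
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depletion estimates per site-year and river-wide annual YOY abundance.

    The removal estimate is fitted to all fish, then partitioned by the
    site-year's mixture YOY fraction (fit-then-partition composition).
    Returns ``(site_estimates, annual_J)``.
    """
    rows = []
    for (site, year), grp in survey.groupby(["site", "year"], sort=True):
        max_pass = int(grp["pass"].max())
        n_passes = max(opts.n_passes, max_pass) if max_pass > opts.n_passes else opts.n_passes
        counts = tuple(
            int((grp["pass"] == p).sum()) for p in range(1, n_passes + 1)
        )
        if len(counts) > 3:
            raise ValueError(f"{site} {year}: more than 3 passes unsupported")
        est = ab.estimate_abundance(
            ab.DepletionCounts(site=str(site), year=int(year), counts=counts)
        )
        rows.append(
            {
                "site": site,
                "year": int(year),
                "n_hat": est.n_hat,
                "p_hat": est.p_hat,
                "method": est.method,
                "total_catch": sum(counts),
                "site_length_m": opts.site_length_m,
            }
        )
    site_df = pd.DataFrame(rows).merge(
        ages_df[["site", "year", "yoy_fraction", "yoy_mean", "yoy_sd"]],
        on=["site", "year"],
        how="left",
    )
    annual = ab.annual_yoy_abundance(site_df, opts.channel_length_m)
    return site_df, annual


def _season_temps(temperature: pd.DataFrame, site: str, year: int):
    """Split one site-cohort temperature series at the October survey date."""
    t = temperature[temperature["site"] == site].copy()
    t["date"] = pd.to_datetime(t["date"])
    start = pd.Timestamp(year, 5, 1)
    end = pd.Timestamp(year + 1, *APRIL_FIRST_MONTH_DAY)
    t = t[(t["date"] >= start) & (t["date"] <= end)].sort_values("date")
    oct_date = pd.Timestamp(year, *OCTOBER_SURVEY_MONTH_DAY)
    to_oct = t.loc[t["date"] <= oct_date, "temp_C"].to_numpy()
    after = t.loc[t["date"] > oct_date, "temp_C"].to_numpy()
    return to_oct, after


def run_growth(
    ages_df: pd.DataFrame, temperature: pd.DataFrame, opts: PipelineOptions
) -> tuple[pd.DataFrame, dict]:
    """Fit (beta, eta_H) per site-year and project YOY sizes to 1 April.

    Returns ``(summary table, {(site, year): GrowthFit})``.
    """
    fits: dict[tuple[str, int], gr.GrowthFit] = {}
    rows = []
    for row in ages_df.itertuples(index=False):
        if not np.isfinite(row.yoy_sd) or row.yoy_sd <= 0:
            warnings.warn(f"{row.site} {row.year}: degenerate YOY sd, skipped")
            continue
        to_oct, after = _season_temps(temperature, row.site, int(row.year))
        if to_oct.size < 30:
            warnings.warn(f"{row.site} {row.year}: temperature series too short, skipped")
            continue
        fit = gr.fit_site_year(
            (row.yoy_mean, row.yoy_sd, row.yoy_count),
            to_oct,
            site=str(row.site),
            year=int(row.year),
            n_fish=opts.cohort_n,
            n_starts=opts.growth_starts,
            seed=opts.seed,
        )
        gr.project_to_april(fit, after)
        fits[(str(row.site), int(row.year))] = fit
        rows.append(
            {
                "site": row.site,
                "year": int(row.year),
                "beta": fit.params.beta,
                "eta_H": fit.params.eta_H,
                "objective": fit.objective_value,
                "at_bound": fit.at_bound,
                "october_mean": fit.october_mean,
                "october_sd": fit.october_sd,
                "april_mean": float(fit.april_lengths_mm.mean()),
                "april_sd": float(fit.april_lengths_mm.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows), fits


def april_lengths_table(growth_fits: dict) -> pd.DataFrame:
    """Long table (site, year, length_mm) of projected 1-April lengths."""
    rows = [
        {"site": site, "year": year, "length_mm": float(v)}
        for (site, year), fit in growth_fits.items()
        if fit.april_lengths_mm is not None
        for v in fit.april_lengths_mm
    ]
    return pd.DataFrame(rows, columns=["site", "year", "length_mm"])


def build_cohort_inputs_from_tables(
    annual: pd.DataFrame,
    annual_j: pd.DataFrame,
    site_df: pd.DataFrame,
    april_df: pd.DataFrame,
    captive_lengths: pd.DataFrame,
) -> lc.CohortInputs:
    """Assemble the aligned annual series for the life-cycle regressions.

    Wild smolt-equivalents pool the per-site April length distributions
    weighted by each site's estimated YOY density; captive ones use the
    release-length samples directly (release sizes are taken as 1-April
    sizes).
    """
    years = annual["year"].to_numpy(dtype=int)
    adults = annual["adults"].to_numpy(dtype=float)
    captives = annual["captives_released"].to_numpy(dtype=float)

    j_map = dict(zip(annual_j["year"], annual_j["J_t"]))
    wild = np.array([j_map.get(y, np.nan) for y in years])

    dens = site_df.copy()
    dens["density"] = dens["n_hat"] * dens["yoy_fraction"] / dens["site_length_m"]
    wild_star = np.full(len(years), np.nan)
    for i, y in enumerate(years):
        sub = dens[dens["year"] == y]
        rates, weights = [], []
        for r in sub.itertuples(index=False):
            apr = april_df.loc[
                (april_df["site"] == r.site) & (april_df["year"] == y), "length_mm"
            ].to_numpy()
            if apr.size == 0:
                continue
            rates.append(
                float((lc.smolt_probability(apr) * lc.marine_survival(apr)).mean())
            )
            weights.append(max(float(r.density), 0.0))
        if rates and np.isfinite(wild[i]):
            w = np.asarray(weights)
            w = w / w.sum() if w.sum() > 0 else np.full(len(rates), 1 / len(rates))
            wild_star[i] = wild[i] * float(np.asarray(rates) @ w)

    captive_star = np.full(len(years), np.nan)
    for i, y in enumerate(years):
        lens = captive_lengths.loc[captive_lengths["year"] == y, "length_mm"].to_numpy()
        if captives[i] == 0:
            captive_star[i] = 0.0
        elif lens.size:
            captive_star[i] = lc.smolt_equivalents(lens, captives[i])
    return lc.CohortInputs(
        years=years,
        adults=adults,
        wild=wild,
        captive=captives,
        wild_star=wild_star,
        captive_star=captive_star,
    )


def build_cohort_inputs(
    annual: pd.DataFrame,
    annual_j: pd.DataFrame,
    site_df: pd.DataFrame,
    growth_fits: dict,
    captive_lengths: pd.DataFrame,
) -> lc.CohortInputs:
    """In-memory variant of :func:`build_cohort_inputs_from_tables`."""
    return build_cohort_inputs_from_tables(
        annual, annual_j, site_df, april_lengths_table(growth_fits), captive_lengths
    )


def run_lifecycle(inputs: lc.CohortInputs, opts: PipelineOptions):
    """Fit both life-cycle models and rank them by AICc.

    Returns ``(ranked scores, {model: TransitionFit}, decomposition df)``
    where the decomposition splits the top model's predictions by origin.
    """
    fits = {}
    scores = []
    for model in (lc.SIZE_CONDITIONAL, lc.FIXED_RATE):
        fit = lc.fit_transition_rates(inputs, model, exclude_years=opts.exclude_years)
        fits[model] = fit
        k = fit.n_params + 1  # coefficients + residual variance
        scores.append(ms.score_from_rss(model, fit.rss, fit.n_years, k))
    ranked = ms.delta_weights_evidence(scores)
    top = fits[ranked[0].name]
    yrs, wild_pred, cap_pred = lc.decompose_origin(top)
    decomposition = pd.DataFrame(
        {
            "year": yrs,
            "observed_adults": top.observed,
            "predicted_adults": top.predictions,
            "wild_pred": wild_pred,
            "captive_pred": cap_pred,
        }
    )
    return ranked, fits, decomposition


def run_recruitment(annual: pd.DataFrame, annual_j: pd.DataFrame, **kwargs):
    """Rank the six density-regulation models on the estimated series."""
    merged = annual.merge(annual_j[["year", "J_t"]], on="year", how="inner").dropna(
        subset=["J_t", "adults"]
    )
    return rec.fit_all_recruitment(
        merged["J_t"].to_numpy(),
        merged["adults"].to_numpy(),
        merged["translocated"].to_numpy(),
        **kwargs,
    )


def run_length_models(annual: pd.DataFrame, ages_df: pd.DataFrame):
    """Rank the YOY-length covariate regressions."""
    mean_len = (
        ages_df.groupby("year")["yoy_mean"].mean().rename("mean_length").reset_index()
    )
    data = annual.merge(mean_len, on="year", how="inner").rename(
        columns={"translocated": "translocations", "flow_cfs": "flow"}
    )
    return rec.fit_length_models(data)


def run_report(
    dataset: SyntheticDataset | dict,
    opts: PipelineOptions | None = None,
    outdir=None,
):
    """Execute every stage and (optionally) write tables and a manifest.

    ``dataset`` is a :class:`SyntheticDataset` or a dict with the same four
    tables.  Returns a dict bundle with every intermediate table, the
    ranked comparisons and the manifest.
    """
    opts = opts or PipelineOptions()
    if isinstance(dataset, SyntheticDataset):
        survey, temperature = dataset.survey, dataset.temperature
        annual, captive_lengths = dataset.annual, dataset.captive_lengths
    else:
        survey = dataset["survey"]
        temperature = dataset["temperature"]
        annual = dataset["annual"]
        captive_lengths = dataset["captive_lengths"]
    _validate_schema(survey, annual, captive_lengths, temperature)

    ages_df = run_ages(survey, opts)
    site_df, annual_j = run_abundance(survey, ages_df, opts)
    growth_df, growth_fits = run_growth(ages_df, temperature, opts)
    inputs = build_cohort_inputs(annual, annual_j, site_df, growth_fits, captive_lengths)
    lc_ranked, lc_fits, decomposition = run_lifecycle(inputs, opts)
    rec_ranked, rec_params = run_recruitment(annual, annual_j, seed=opts.seed)
    len_ranked, _ = run_length_models(annual, ages_df)

    bundle = {
        "ages": ages_df,
        "site_abundance": site_df,
        "annual_abundance": annual_j,
        "growth": growth_df,
        "lifecycle_scores": lc_ranked,
        "lifecycle_fits": lc_fits,
        "lifecycle_table": ms.comparison_table(lc_ranked),
        "decomposition": decomposition,
        "recruitment_table": ms.comparison_table(rec_ranked),
        "recruitment_params": rec_params,
        "length_table": ms.comparison_table(len_ranked),
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "ages.csv": ages_df,
            "site_abundance.csv": site_df,
            "annual_abundance.csv": annual_j,
            "growth_fits.csv": growth_df,
            "lifecycle_comparison.csv": bundle["lifecycle_table"],
            "adult_decomposition.csv": decomposition,
            "recruitment_comparison.csv": bundle["recruitment_table"],
            "length_comparison.csv": bundle["length_table"],
        }
        digest = hashlib.sha256()
        for name, df in tables.items():
            text = df.to_csv(index=False, float_format="%.10g")
            (out / name).write_text(text)
            digest.update(name.encode())
            digest.update(text.encode())
        manifest = {
            "package": "condsmolt",
            "version": __import__("condsmolt").__version__,
            "seed": opts.seed,
            "options": asdict(opts),
            "output_sha256": digest.hexdigest(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        bundle["manifest"] = manifest
    return bundle


def _validate_schema(survey, annual, captive_lengths, temperature):
    schemas = {
        "survey": (survey, {"site", "year", "pass", "length_mm"}),
        "annual": (annual, {"year", "adults", "captives_released", "translocated", "flow_cfs"}),
        "captive_lengths": (captive_lengths, {"year", "length_mm"}),
        "temperature": (temperature, {"site", "date", "temp_C"}),
    }
    for name, (df, cols) in schemas.items():
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
        bad = df[list(cols)].isna().any(axis=1)
        if bad.any():
            raise ValueError(
                f"{name} table has missing values in rows {list(df.index[bad][:5])}"
            )
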