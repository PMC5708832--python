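# condsmolt

Retrospective population analysis for anadromous steelhead
(*Oncorhynchus mykiss*) monitoring data, built around the hypothesis of
**size-conditional smolting and marine survival**: juveniles transform into
ocean-going smolts only if they grow past a physiological size threshold,
and their early marine survival rises steeply with length at ocean entry.
Under that hypothesis, interventions that raise juvenile abundance can
backfire by increasing competition, slowing growth and suppressing adult
returns — a question this package lets you pose quantitatively against a
fixed-rate null in which every juvenile has the same chance of returning.

It is aimed at fisheries and population ecologists with the standard
monitoring portfolio: October multi-pass electrofishing length samples,
daily water temperatures, and annual series of adult counts, captive
releases, translocations and streamflow.

## The models

**Age structure.** Site-year fork lengths are a K-component normal mixture
(K ∈ 1..4 chosen by BIC); the smallest-mean component is the
young-of-the-year (YOY) class.

**Abundance.** Site abundance comes from removal (depletion) sampling:
the Zippin constant-capture-probability maximum-likelihood estimator for
3 passes, the Seber–LeCren closed form N̂ = c₁²/(c₁−c₂) for 2.  Mean YOY
density (fish/m) across sites × 40 km of channel gives the annual wild
YOY abundance J_t.

**Growth.** An individual-based daily model with size-asymmetric
competition: a competitor of length λ imposes cost exp(β(λ−L)) on a focal
fish of length L, and each fish's specific mass growth rate is
g_max·φ(T)·η_H / (1 + load), with φ a unimodal temperature response
(within 85% of maximum on 12–18 °C) and η_H the site-year food
availability.  (β, η_H) are fitted to the observed October YOY mean/sd and
used to project sizes to 1 April.

**Life cycle.** Predicted adults under the fixed-rate model

    A_t = q₁(0.53·J_{t−1} + 0.47·J_{t−2}) + q₂(0.53·C_{t−1} + 0.47·C_{t−2})

versus the size-conditional model, which replaces J and C by
smolt-equivalents J*, C* — abundance weighted by the mean over fish of
smolting probability (logistic in April length, threshold 120 mm,
dispersion 10 mm) times marine survival
min{0.35, 0.84/(1+exp(8.657−0.0369·L))}.  Apparent transition rates q are
OLS coefficients (no intercept, sign-free) that confound vital rates with
the fixed sampling biases of the monitoring series; helper arithmetic
converts them to bias-corrected expectations.  Models are compared by
AICc, Akaike weights and evidence ratios, as are six density-regulation
models for J_t and seven covariate regressions for YOY length.

**Synthetic data.** A first-class generator emulates the full monitoring
portfolio with known ground truth (density 1.96 YOY/m, annual CV 46%,
spatial CV 28%, YOY fraction 0.77, adults forward-simulated from the
size-conditional truth), so every estimator is testable for parameter
recovery without access to any real dataset.

## Worked example

```python
from condsmolt.synthetic_data import ScenarioConfig, generate_scenario
from condsmolt.pipeline import PipelineOptions, run_report

ds = generate_scenario(ScenarioConfig(sites=("site_1", "site_2"), seed=5, cohort_n=100))
bundle = run_report(ds, PipelineOptions.fast(seed=3))
print(bundle["lifecycle_table"][["Model", "AICc", "Delta", "Wt"]])
```

prints

```
              Model        AICc      Delta            Wt
0  size_conditional  139.856930   0.000000  1.000000e+00
1        fixed_rate  188.774131  48.917201  2.386518e-11
```

i.e. on data whose truth is size-conditional (with food availability
declining in the downstream site), the size-conditional model is selected
with essentially all of the Akaike weight; the fitted transition rates
(q₃≈1.32, q₄≈0.67) bracket the generating values (1.178, 0.594).  The
same run decomposes predicted adults by origin, showing the captive share
rising as wild April sizes fall.

The numbered scripts under `analysis/` run the same stages on the default
nine-site scenario and write their tables under `results/`:
`01_simulate.py` → `02_age_structure.py` → ... → `07_report.py`.

A command-line entry point wraps the same stages:

```sh
condsmolt simulate --out data/ --seed 1
condsmolt report --data data/ --out report/ --seed 1
```

## Acceptance script

`scripts/acceptance.py` recomputes, from the package's own curve
arithmetic, the two closed-form headline quantities of the analysis — the
smallest whole-millimetre length at which the 0.35 marine-survival ceiling
binds (verified independently by an integer-length scan) and the smolting
probability at the threshold length — and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
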