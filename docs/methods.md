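# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `condsmolt`, and what the synthetic-data tests do and do
not establish.

## Age-structure decomposition

Site-year fork-length samples are modelled as mixtures of K univariate
normals, K ∈ {1..4} selected by BIC with parameter count p = 3K − 1
(K means, K standard deviations, K − 1 free weights) and plain per-fish
sample size n.  Components are interpreted by rank of their means:
smallest = young-of-the-year (YOY), then age 1, then age 2+.  EM details:

- initialization by quantile-seeded 1-D k-means; 20 restarts with seeded
  jitter (first restart unjittered, so K = 1 needs no restarts);
- convergence at 1e−6 absolute log-likelihood change, max 500 iterations;
- component sd floored at 1 mm — fork length is measured to the
  millimetre, so narrower components are numerical artefacts; a floored
  fit is flagged;
- BIC ties break toward smaller K (parsimony);
- per-fish classes use hard max-posterior assignment (posterior
  responsibilities are also retained).

The EM is implemented in-package because downstream checks require the
per-iteration log-likelihood trace and the exact BIC accounting; the
test-suite cross-checks it against an independent library implementation.
Uncaptured fish are assumed to follow the same mixture, so the fitted YOY
fraction applies unchanged to the depletion-corrected site abundance
(fit-then-partition).

## Removal abundance

Three-pass estimates use the constant-capture-probability removal model.
We maximize the profile likelihood over p with N profiled out as
N(p) = T/(1 − (1−p)^k), using the continuous-N (Stirling) form of the
factorial terms; the maximizer of that profile is exactly the classical
removal estimator (the root of the Zippin score equation), returning
N̂ = 120, p̂ = 0.5 on perfectly geometric catches (60, 30, 15).  The exact
discrete-N maximum-likelihood point differs slightly (N̂ ≈ 118.7 on the
same counts); we follow the classical estimator, which is what the
removal-sampling literature and monitoring practice report.  When catches
show no depletion signal (mean removal index ≥ (k−1)/2) there is no
interior maximum and the estimator falls back to the total catch with an
explicit method flag.  Two-pass site-years use Seber–LeCren
N̂ = c₁²/(c₁−c₂), falling back likewise when c₁ ≤ c₂.

Annual expansion: J_t = mean across surveyed sites of
(N̂ · YOY fraction / site length) × channel length.  Channel length
defaults to 40 km (upper dam to estuary), site reach length to 100 m.

## Growth kernel

The published bioenergetics formulation this pipeline is patterned on is
not fully specified in accessible form, so the package uses a minimal
kernel that preserves the roles of its ingredients:

- temperature response φ(T) = exp(−(T−15)²/c) with c = 9/ln(1/0.85)
  ≈ 55.4, calibrated so φ = 0.85 exactly at 12 and 18 °C (the band of
  near-maximal salmonid growth) and ≈ 0.52 at the 21 °C stress threshold;
- asymmetric competition C(L|λ) = exp(β(λ−L)); a fish's load is the mean
  over its competitors (self excluded), so load ≡ 1 when β = 0 or when a
  fish has no competitors, and η_H is comparable across sites of
  different density;
- specific daily mass growth r = g_max · φ(T) · η_H / (1 + load), with
  g_max = 0.025 d⁻¹ fixed; mass and length are coupled by
  m = 10⁻⁵ L³ (condition factor), so lengths never decrease.

Cohorts emerge on 1 May at N(28, 2) mm; the October survey is dated
15 October; projection runs to 1 April with (β, η_H) frozen (seasonal
changes in food and competition assumed negligible) and without
overwinter mortality, which is deliberately absorbed into the life-cycle
transition rate.  Note that with this kernel η_H ≈ 1.5–2.0, not ≈ 1,
yields the realistic 60–90 mm October range; η_H is a free scalar and its
absolute scale carries no meaning beyond the kernel.

Fitting minimizes the summed squared *relative* errors of the simulated
October mean and sd against the observed YOY component, over
β ∈ [0, 0.2] mm⁻¹ × η_H ∈ (0, 10], from 8 Latin-hypercube starts with
bounded L-BFGS-B refinement (ftol 1e−6).  The simulated cohort (200 fish
by default) is drawn once per fit, making the objective deterministic;
solutions on the parameter-box boundary are flagged.  A compiled (numba)
kernel accelerates the daily loop; a reference numpy path implements the
identical update and the tests assert their agreement.

## Life-cycle models

Both models are linear in the apparent transition rates with the fixed
(0.53, 0.47) split of one- versus two-year ocean residents, no intercept
and no sign constraint.  Wild smolt-equivalents pool the per-site April
length distributions weighted by estimated site YOY density; captive
release lengths are taken as 1-April lengths unchanged.  Usable years are
those with both lags and an adult count; specific years (e.g. a season
with blocked migratory access) can be excluded by configuration.  A
degenerate predictor column (e.g. no captive program) is dropped with a
flag rather than producing a singular solve.

Bias arithmetic: with spatially even spawning, ladder counts that omit
44.8% of accessible habitat imply an adult-count bias of −0.448; surveys
omitting 61.5% of stream km imply a juvenile bias of −0.615.  The wild
transition expected from biases alone is (1−0.448)/(1−0.615) ≈ 1.43; the
per-spawner production correction divides by the printed ratio 1.41.
Both constants are kept and each is used exactly where the original
analysis used it; the 1.41/1.43 discrepancy is surfaced rather than
reconciled.

## Model selection

AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with the residual variance
counted in k (a two-coefficient regression has k = 3).  Δ-AICc bands:
< 2 substantial support, 2–4 intermediate, > 4 considerably less, > 10
essentially none.  Akaike weights, evidence ratios and summed-weight odds
follow the standard information-theoretic definitions.  The
constant-inclusive Gaussian log-likelihood is reported alongside; note
that published rankings of this kind sometimes print log-likelihoods and
AICc values that cannot be reconciled under a single n — our tables are
self-consistent by construction.

## Recruitment and length models

The six density-regulation models are fitted by bounded trust-region
nonlinear least squares from 16 data-scaled log-spaced starts, with
bounds K ∈ (0, 10⁷], r ∈ (0, 10⁴], s ∈ [0, 10]; asymptotic standard
errors come from the Jacobian at the optimum.  The logistic-capacity
prediction is floored at zero (with a warning) where r·A > K.  YOY-length
regressions are ordinary least squares with intercept over all seven
predictor combinations of flow, adults and translocations; condition
numbers are reported, collinear designs are never dropped.

## Synthetic world

The generator's defaults state a world patterned on two decades of
monitoring of a central-California coastal steelhead river:

| quantity | default | basis |
|---|---|---|
| years / sites | 1996–2013, 9 sites | monitoring design |
| YOY density | 1.96 fish/m; annual CV 46%, spatial CV 28% | reported survey summaries |
| YOY fraction | 0.77 (non-YOY split 0.8/0.2 into age 1 / 2+) | reported classification |
| capture probability | 0.5 per pass, 3 passes | typical electrofishing |
| temperature | 13 ± 7 °C sinusoid, phase day 110, noise sd 0.5 | observed monthly means; summer stays below 21 °C |
| growth truth | β = 0.012; η_H 1.7→1.35 (pulse then decline) downstream, 1.5 upstream | reproduces the inferred food-availability pattern and 60–90 mm October sizes |
| transitions | (q₃, q₄) = (1.178, 0.594); split (0.53, 0.47) | reported estimates |
| captive program | ~3000/yr; release length median 95→200 mm | reported trend |
| adult noise | additive Gaussian sd 30, truncated at 0 | least squares implies Gaussian errors |

Density, temperature, cohort, sampling and annual streams draw from
separate child RNGs of the scenario seed, so regeneration is
bit-identical and the truth record suffices to recompute every
intermediate quantity.

What the generator does **not** emulate: fish movement between sites,
overdispersed or size-selective capture, iteroparity and 3–4-year ocean
residents, hydrological realism of the flow series, and any feedback from
adults to juvenile density (J_t is exogenous to A_t, so recruitment-model
rankings on default scenarios reflect that stated independence).  A green
end-to-end test therefore establishes that the estimators recover the
stated world, not that the stated world captures every feature of real
monitoring data.

## Known limitations

- **Joint 2-SE recovery bars.**  With ~18 annual observations, the
  per-parameter 2-SE coverage of the transition-rate and recruitment
  fits is at its nominal level (≈93–95%, matching P(|t₁₄..₁₅| ≤ 2)), but
  the *joint* event "every parameter within 2 SE" has probability ≈0.87
  for two parameters and ≈0.86 for three under weak error correlation.
  Test suites that demand ≥90% joint recovery at this sample size fail
  for that arithmetic reason alone; the failure messages report the
  per-parameter rates so the distinction is visible.
- The growth kernel is a stand-in for a fuller bioenergetics model; only
  qualitative patterns of the fitted η_H series (pulse then decline) are
  meaningful, never its absolute scale.
- April sizes of wild fish inherit the frozen-parameter projection;
  faster spring growth would shift smolt-equivalents upward coherently
  across years, which the transition rates largely absorb.
- The pipeline assumes a 3-pass protocol when padding zero-catch passes;
  a genuine 2-pass site-year is recognized only if the survey table
  contains no third pass for it and the protocol option is set to 2.
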