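# Methods

This note documents the models, conventions and design choices behind
`fluxefp`: what is computed, under which assumptions, and what the synthetic
data used by the tests can and cannot establish.

## The quantity being estimated

Ecosystem photosynthetic capacity is treated as an *ecosystem functional
property*: a slowly varying characteristic of the vegetation, derived from
half-hourly eddy-covariance GPP in a way that standardizes away short-term
meteorology.  The estimator family comes from light-response curves — GPP as
a function of incoming radiation Q, where Q is either PAR (incoming
photosynthetically active radiation) or APAR (absorbed PAR = FAPAR × PAR,
folding in canopy structure).

### Light-response model

The nonrectangular hyperbola (NRH)

    GPP(Q) = [ αQ + Amax − √((αQ + Amax)² − 4 θ α Q Amax) ] / (2θ)

is the positive root of θ·GPP² − (αQ + Amax)·GPP + αQ·Amax = 0, with

| parameter | meaning | units | box constraint |
|---|---|---|---|
| α | initial (quantum-yield) slope | μmol CO₂ / μmol photons | [1e−6, 0.5] |
| Amax | plateau | μmol CO₂ m⁻² s⁻¹ | [0.1, 100] |
| θ | curvature | – | [0, 1] |

θ = 0 is evaluated through its analytic limit, the rectangular
(Michaelis–Menten) hyperbola αQ·Amax/(αQ + Amax), avoiding 0/0; θ = 1 gives
the Blackman limit min(αQ, Amax).  The implementation is exact at both
ends (tested against the closed forms) and monotone in Q and Amax.

The box constraints are wide physical bounds; they are not stated anywhere
authoritative and are configurable.

### Window fitting

Parameters are estimated by least squares on 5-day moving windows (center
day ± 2), attributed to the center day, stepping one day at a time.  The
optimizer is L-BFGS-B (quasi-Newton with box constraints) with multi-start
initialization: 5 starts with θ ∈ {0.1 … 0.9}, α from a low-light slope
heuristic, Amax from the 95th percentile of window GPP; the lowest residual
sum of squares wins.  Windows with fewer than 20 usable half-hours (default,
configurable) return a non-converged record rather than raising.  On
noiseless synthetic windows the fit recovers (α, Amax, θ) to ≲0.01%.

Days are retained downstream only when the fit R² = 1 − SSE/SST exceeds 0.6
(strict); this doubles as a growing-season filter.

### Daily capacity quantities

From each converged fit:

* **Amax** — the plateau parameter itself;
* **GPPsat** — the fitted curve at saturating light, Qsat = 2110
  μmol m⁻² s⁻¹ for PAR (the PAR equivalent of Rg = 1000 W m⁻²) and 2000 for
  APAR;
* **GPPcum** — ∫₀^Qsat GPP(Q) dQ by adaptive quadrature (tested against a
  10⁴-node trapezoid oracle and the θ = 1 closed form).

APAR-driven variants carry the suffix `.structure`.  GPPsat and GPPcum are
interpolations within the observed light range and are markedly more robust
to flux noise than Amax, which extrapolates beyond the data whenever high
light is scarce (windows whose 95th-percentile light is below half of Qsat
are flagged `low_light_window`).

## Input screening

* PAR = 2.11 × Rg (Rg in W m⁻², PAR in μmol m⁻² s⁻¹).
* Only daytime (Rg > 10 W m⁻², strict) and measured (not gap-filled)
  half-hours enter the fits.
* Site-year screening: an April–September day is *bad* when more than 80%
  of its 48 expected half-hours are gaps (missing records count as gaps);
  the site-year is dropped when more than 25% of the 183 calendar days are
  bad.  Both thresholds are strict, matching "more than" wording; the 25%
  rule is applied against all 183 days, not only days with data — the
  conservative reading of an ambiguous rule.
* Exclusion of disturbed or very dry sites is a metadata flag in the
  configuration, never inferred from data.

## FAPAR processing

16-day satellite FAPAR for the tower pixel is gap-filled from neighbor
pixels whose association with the central series exceeds 0.75 — distance
correlation by default (Pearson switchable; which of the two the original
procedure used is ambiguous, so both are exposed).  Donors are an explicit
input list rather than a spatial query.  Fills are affine-bias-corrected
(central regressed on donor over shared dates; raw substitution
switchable), and provenance records the donor of every filled step.
Residual gaps use a deliberately simple fallback — same-season climatology
across years, then linear interpolation — in place of heavier
spatiotemporal fillers; it is labeled as such and clamped to [0, 1].

Daily FAPAR comes from a cubic smoothing spline with its penalty chosen by
generalized cross-validation, clamped to [0, 1]; on noiseless
double-logistic seasonality sampled 16-daily, the daily RMSE against truth
is <0.001 (tested at 0.02).  Annual maximum LAI is the 90th percentile of
the year's 16-day LAI retrievals.

**Percentile convention (repo-wide):** linear interpolation between order
statistics at rank h = (n−1)·p + 1 — identical in LAI, annual capacity
extraction, and CV summaries.

## Annual extraction and estimator comparison

Annual capacity per site-year is the maximum or a percentile (90th–60th) of
the retained daily series; at least 10 retained days are required (else the
year is missing, with a reason).  Interannual variability is
CV = sample standard deviation (n−1) / mean across years.  Estimators ×
extraction percentiles are compared by the distribution of CV across sites
with ≥5 years; the percentile minimizing mean CV is flagged.  On heavy-tailed
synthetic daily series the 90th percentile is less variable between years
than the maximum in ≈98% of site-histories — the robustness argument for
percentile extraction.

## Community traits

Species-level leaf traits aggregate to site level as community-weighted
means (CWM = Σ abundanceᵢ·valueᵢ); within-species replicates are averaged
to one species value first, matching the species-mean pathway of global
trait databases.  Missing species are dropped with abundance
renormalization.  Derived stoichiometry: C/N = c_mass/n_mass (g/g);
N_area = n_mass/SLA, which is already g m⁻² when n_mass is mg g⁻¹ and SLA
mm² mg⁻¹ (SLA is implemented in mm² mg⁻¹ — the only dimensionally coherent
reading of the conventional "mm/mg" shorthand); N% = n_mass/10.  Provided
per-area values take precedence over derived ones, with a warning when they
disagree by >5%.  An unweighted (simple species mean) variant supports
abundance-uncertainty sensitivity checks.

## Linking capacity to traits

Per-site capacity scalars (multi-year mean, or the trait-sampling year's
value) are related to CWM traits under three synchronization scenarios:
(multiyear mean, database traits), (multiyear mean, in-situ traits),
(sampling year, in-situ traits).  For each: OLS slope/intercept ± SE,
R²/adjusted R², overall F p-value; distance correlation (Székely
double-centering, shared implementation, V-statistic form); leave-one-out
cross-validation summarized as modeling efficiency EF = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²
(≤1, negative when worse than the mean) and RRMSE = 100·RMSE/mean(y)
(denominator choice switchable).  ANCOVA F-tests compare scenarios: the
x:group interaction tests slope homogeneity, the group term intercept
differences; the interaction test holds its nominal 5% level within
[0.03, 0.07] over 1000 equal-slope simulations.

A permutation test asks whether using the trait-sampling year's capacity
beats an arbitrary year: the observed R² is ranked against B draws giving
each site a uniformly random available year, with the +1-corrected
empirical p (never exactly 0).

### Stepwise trait selection

Candidates are built from each base predictor v (traits + LAI) as
{v, v², √v, log v} (log dropped unless all values are positive, √ unless
non-negative) plus every ordered ratio of *base* variables — ratios of
transformed variables are excluded to keep the set finite.  Ratios that
replicate a measured trait through a stoichiometric identity
(c_mass/n_mass ≡ C/N, p_mass/SLA ≡ P_area, n_mass/SLA ≡ N_area) are
deduplicated.

Selection is bidirectional stepwise under AIC = n·ln(RSS/n) + 2k (additive
constants dropped — only differences matter), starting from the
intercept-only model, with model size capped at n/5 terms.  Two
robustifications address the near-collinearity of transform/ratio
candidates at small n: a one-for-one *replacement* move (so a proxy such as
√(C/N) can be swapped for the true term even at the size cap), and
deterministic restarts from the 5 best single-term models, the lowest final
AIC winning.  Every move strictly decreases AIC, so the search terminates;
ties break by candidate order.  Rank-deficient additions are skipped, which
also blocks duplicated columns.

**Identifiability caveat.**  The variable-selection recovery experiment in
the acceptance suite (true model GPPsat = 41.62 − 0.39·C/N + 23.94·P_area²,
n = 18 sites, σ = 0.01 noise) succeeds in ≈98% of seeds *when P varies
independently of N across species* (`p_coupling="independent"`, lognormal
spread ≈ 0.2–6 mg g⁻¹).  Under the generator's default stoichiometric
coupling (P tied to N through an N:P ratio ≈ 14 ± 2), ratio candidates
built from N carry most of the P signal and the true terms are *not*
identifiable at n = 18 — stepwise then picks collinear proxies with nearly
the same fit.  This is a property of the candidate set and sample size, not
of the search: real multi-site trait data sit closer to the coupled case,
and selected "best traits" there should be read as representatives of
correlated clusters.

## Synthetic data

The generators supply every pipeline input with known truth; one integer
seed drives named, independently spawned RNG streams (clearness, year
effects, flux noise, gaps, FAPAR, traits), so regeneration is bit-identical
and stages can be re-drawn independently.

* **Radiation** — sinusoidal day arc; daylength 12 ± 12·`latitude_proxy`·
  sin(seasonal phase) hours; noon amplitude 10→100% of `rg_max_summer`
  (800 W m⁻² default) from midwinter to midsummer; day-level multiplicative
  clearness factor 1 − 0.3·Beta(1.5, 4), bounded in (0, 1].  No solar
  geometry beyond this; no weather covariates.
* **GPP** — NRH with double-logistic α(t), Amax(t) (defaults: green-up day
  110, senescence day 280, steepness 0.08 d⁻¹; α floor 15%, Amax floor 5%
  of peak; α_peak 0.04, Amax_peak 28, θ 0.6); per-year lognormal mean-one
  multiplier on Amax (`year_effect_sd`); heteroscedastic noise with
  sd = `noise_scale` × modeled GPP (Gaussian default, Laplace option) —
  random flux error scaling with flux magnitude.  The noise magnitude at
  real towers is not pinned by any source used here; the 0.1 default is a
  free choice flagged as such.  Gaps mix geometric-length blocks (mean 12
  half-hours, half the budget) with i.i.d. singletons, hitting the target
  fraction exactly — enough block structure to exercise the per-day 80%
  rule.
* **FAPAR** — double-logistic seasonality in [0.10, 0.85]; correlated
  neighbors = central + Gaussian noise; independent neighbors ~ Beta(2, 2)
  to exercise the donor screen; gaps injected into the central pixel; LAI
  by Beer–Lambert inversion (k = 0.5).
* **Traits** — per-site community N% uniform in [1.2, 3.2]; true GPPsat =
  15.67 + 7.25·N% + ε (the reported magnitudes for the GPPsat–N% relation;
  ε sd 3.0 default); species N% scattered (sd 0.25) and re-centered so the
  CWM hits the target exactly; C ≈ 470 ± 25 mg g⁻¹, lognormal SLA (median
  12 mm² mg⁻¹), δ13C ≈ −28 ± 1.5‰; a "database" copy of each species adds
  independent N% bias (sd 0.2%) to mimic global-database lookup.  The
  multi-site study generator inverts the NRH at Qsat to choose each site's
  Amax so that its true GPPsat obeys the trait relation, making all stages
  coherent end to end.

What the synthetic world does **not** emulate: temperature/VPD controls on
GPP (the window fit absorbs them in reality), autocorrelated weather,
footprint/pixel mismatch, disturbance history, instrument drift, or
nonlinear trait–capacity relations.  Passing tests therefore establish the
*procedure* — screening, fitting, extraction, aggregation, inference — not
the field accuracy of any capacity estimate.

## Problem sizes and numerical choices

* Test and acceptance runs use desk-scale studies — e.g. 4–10 sites × 2
  years with windows stepped every 7 days for end-to-end checks, 200
  windows for recovery statistics, 100 seeds for selection recovery, 1000
  simulations for test calibration — chosen as the package's own default
  experiment sizes; all are configuration fields.
* Optimizer tolerances are L-BFGS-B defaults; quadrature tolerance 1e−6;
  percentile and CV conventions as above; the ANCOVA uses exact F-tests via
  nested-model comparison.
* Degenerate inputs are contracts, not crashes: empty windows and thin
  years return flagged missing values; constant series are exact
  (smoothing spline short-circuits); undefined statistics (CV of
  non-positive mean, dcor of constants, RRMSE at zero mean) raise
  informative errors.

## Known limitations

* The neighbor-screen threshold (0.75) is applied to distance correlation
  by default although the original wording ("r > .75") could equally mean
  Pearson; both are one switch apart and agree closely on smooth seasonal
  series.
* The fallback FAPAR filler is intentionally simple; sites with a single
  year and long gaps fall back to linear interpolation, which flattens
  seasonal structure.
* Amax from low-light windows is reported but untrustworthy (flagged);
  downstream summaries should prefer GPPsat/GPPcum, which is exactly what
  the CV comparison recommends.
* Backward-only stepwise starts from the first `max_terms` candidates (a
  full-model start is rank-deficient whenever candidates outnumber
  observations); bidirectional is the default and the tested mode.
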