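# fluxefp

Ecosystem photosynthetic capacity from eddy-covariance GPP — and its links
to community-weighted leaf traits.

`fluxefp` is for flux-tower and trait ecologists who want a reproducible
path from half-hourly gross primary productivity (GPP) and radiation to a
per-site *ecosystem functional property* — photosynthetic capacity under
standardized light — and from there to leaf-trait explanations of its
across-site variability.  Because the canonical inputs (flux-network
half-hourly archives, global trait databases, satellite FAPAR) are
access-restricted, the package ships a synthetic-data generator with known
ground truth that feeds every stage, so the full pipeline is testable and
demonstrable without any download.

## The method

GPP responds to incoming radiation Q (PAR, or APAR = FAPAR × PAR) along the
nonrectangular hyperbola

    GPP(Q) = [αQ + Amax − √((αQ + Amax)² − 4θαQAmax)] / (2θ)

with initial slope α, plateau Amax and curvature θ ∈ [0, 1] (θ→0:
Michaelis–Menten; θ=1: Blackman).  The pipeline:

1. **QC** — PAR = 2.11·Rg; keep daytime (Rg > 10 W m⁻²), measured
   half-hours; drop site-years where >25% of April–September days have
   >80% gaps.
2. **FAPAR** — gap-fill the tower pixel from neighbor pixels correlated
   >0.75 (distance correlation), smooth to daily with a GCV spline, form
   APAR; annual maximum LAI = 90th percentile of the year's retrievals.
3. **Fit** — least squares in 5-day moving windows (L-BFGS-B, box
   constraints, multi-start), one parameter set per day; keep days with
   fit R² > 0.6.
4. **Extract** — six estimators (Amax, GPPsat, GPPcum × PAR/APAR), where
   GPPsat = GPP(Qsat) at Qsat = 2110 (PAR) / 2000 (APAR) μmol m⁻² s⁻¹ and
   GPPcum = ∫₀^Qsat GPP dQ; annual value = max or a percentile (90th–60th)
   of the daily series; pick the extraction minimizing interannual CV
   (sd/mean across years, sites with ≥5 years).
5. **Link** — community-weighted mean (CWM) traits per site; OLS, distance
   correlation, leave-one-out EF/RRMSE across three
   capacity–trait synchronization scenarios; ANCOVA between scenarios; a
   year-resampling permutation test; stepwise-AIC selection over traits,
   their powers/logs and ratios.

See `docs/methods.md` for conventions, defaults, and limitations.

## Worked example

```python
from fluxefp import (SiteSimConfig, simulate_site_fluxes, filter_daytime_measured,
                     par_from_rg, fit_window, derive_daily, fit_site, annual_extract)

cfg = SiteSimConfig(site_id="DEMO", n_years=1, seed=4,
                    noise_scale=0.1, gap_fraction=0.1)
flux, truth = simulate_site_fluxes(cfg)          # half-hourly GPP/Rg + truth
rec = filter_daytime_measured(flux)
rec = rec.assign(par=par_from_rg(rec["rg"].to_numpy()))

p = fit_window(rec, "2005-07-10", "PAR")         # one 5-day window
print(f"alpha={p.alpha:.4f} amax={p.amax:.2f} theta={p.theta:.3f} "
      f"r2={p.r2:.3f} n={p.n_obs}")
d = derive_daily(p)
print(f"gpp_sat={d['gpp_sat']:.2f} gpp_cum={d['gpp_cum']:.0f}")

daily = fit_site(rec, "PAR", step_days=7)        # whole year, weekly windows
print(f"annual GPPsat (90th pct) = {annual_extract(daily, 2005, 90):.2f}"
      f"   truth at peak = {truth.gppsat_by_year[2005]:.2f}")
```

prints

```
alpha=0.0359 amax=24.87 theta=0.810 r2=0.855 n=145
gpp_sat=22.97 gpp_cum=37131
annual GPPsat (90th pct) = 23.96   truth at peak = 24.13
```

One mid-July window (145 usable half-hours, 10% proportional flux noise)
yields a light-saturated capacity GPPsat ≈ 23 μmol CO₂ m⁻² s⁻¹ and a curve
integral GPPcum ≈ 3.7 × 10⁴ μmol-scale units; the annual 90th-percentile
extraction (23.96) recovers the generator's true peak-season capacity
(24.13) to within ~1% despite noise and gaps.  Note Amax (24.87) differs
from GPPsat: the plateau extrapolates beyond the observed light range and
is the least robust of the estimators — which is why the CV comparison
recommends GPPsat/GPPcum.

The same flow runs from the shell:

```bash
fluxefp run-all --out results/ --seed 1          # synthetic end-to-end study
fluxefp simulate --out data/ --seed 1            # write synthetic input CSVs
fluxefp qc data/flux_SYN-001.csv --out screen.csv
```

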