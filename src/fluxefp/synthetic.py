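"""Synthetic flux, FAPAR and trait data with known ground truth.

The real inputs this pipeline was designed around — half-hourly
eddy-covariance GPP, 16-day satellite FAPAR/LAI, and site species-trait
tables — are access-restricted, so every generator here emulates their
statistical structure with a known truth object, making each downstream
stage testable end to end:

* **Radiation**: a sinusoidal day arc whose length and amplitude follow a
  seasonal cycle set by ``latitude_proxy``, with multiplicative day-level
  clearness noise in (0, 1].
* **GPP**: the nonrectangular hyperbola driven by PAR with a double-logistic
  seasonal trajectory of α(t) and Amax(t), lognormal year effects on Amax,
  and heteroscedastic noise (sd proportional to the modeled flux — flux
  random error scales with flux magnitude; Laplace optional).  Gaps are a
  mixture of i.i.d. singletons and geometric-length blocks.
* **FAPAR**: double-logistic seasonality for a central pixel, correlated
  neighbors (central + noise), optional independent neighbors to exercise
  the donor screen, and injected gaps; LAI by Beer–Lambert inversion.
* **Traits**: multi-site species tables whose community-weighted N% relates
  to true GPPsat by a configurable linear relation (defaults: intercept
  15.67, slope 7.25 — the magnitudes reported for the GPPsat–N% relation).

One integer seed drives named, independently spawned RNG streams
(clearness, year effects, flux noise, gaps, fapar, traits) so stages can be
regenerated independently and bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lightresponse import QSAT_PAR, nrh_gpp
from .qc import PAR_PER_RG, par_from_rg

__all__ = [
    "SiteSimConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "double_logistic",
    "simulate_radiation",
    "simulate_site_fluxes",
    "simulate_fapar_pixels",
    "simulate_trait_sites",
    "simulate_study",
]

#: GPPsat–N% relation used as the default trait-generator truth.
DEFAULT_TRAIT_INTERCEPT = 15.67
DEFAULT_TRAIT_SLOPE = 7.25

_STREAMS = ("clearness", "year_effects", "flux_noise", "gaps", "fapar", "traits")


@dataclass(frozen=True)
class SiteSimConfig:
    """Configuration of one synthetic flux site."""

    site_id: str = "SYN-001"
    n_years: int = 1
    start_year: int = 2005
    latitude_proxy: float = 0.35  # seasonal daylength amplitude, 0–1
    rg_max_summer: float = 800.0  # W m⁻², clear-sky midsummer noon
    alpha_peak: float = 0.04  # μmol CO₂ per μmol photons
    amax_peak: float = 28.0  # μmol CO₂ m⁻² s⁻¹
    theta_true: float = 0.6
    season_start: float = 110.0  # day of year, green-up midpoint
    season_end: float = 280.0  # day of year, senescence midpoint
    season_steepness: float = 0.08  # 1/day
    clearness_noise: float = 0.3  # scale of (1 − clearness); 0 disables
    noise_scale: float = 0.1  # flux noise sd as fraction of modeled GPP
    noise_kind: str = "gaussian"  # "gaussian" | "laplace"
    gap_fraction: float = 0.1
    year_effect_sd: float = 0.0  # lognormal sd of interannual Amax multiplier
    seed: int = 0

    def validate(self) -> None:
        if self.rg_max_summer <= 0:
            raise ValueError("rg_max_summer must be positive")
        if not 0.0 <= self.theta_true <= 1.0:
            raise ValueError("theta_true must lie in [0, 1]")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must lie in [0, 1]")
        if self.alpha_peak <= 0 or self.amax_peak <= 0:
            raise ValueError("alpha_peak and amax_peak must be positive")
        if not 0.0 <= self.latitude_proxy <= 1.0:
            raise ValueError("latitude_proxy must lie in [0, 1]")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.noise_scale < 0 or self.clearness_noise < 0:
            raise ValueError("noise scales must be non-negative")
        if self.noise_kind not in ("gaussian", "laplace"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated site."""

    site_id: str
    dates: pd.DatetimeIndex  # daily
    alpha_daily: np.ndarray
    amax_daily: np.ndarray  # includes the year multiplier
    theta: float
    year_multiplier: dict[int, float]
    gppsat_by_year: dict[int, float]  # NRH at Qsat with peak-season α, Amax


def _rng(config: SiteSimConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def double_logistic(doy, start: float, end: float, steepness: float) -> np.ndarray:
    """Double-logistic phenology in [0, 1]: rise at ``start``, fall at
    ``end`` (days of year), normalized to peak at 1."""
    doy = np.asarray(doy, dtype=float)
    up = 1.0 / (1.0 + np.exp(-steepness * (doy - start)))
    down = 1.0 / (1.0 + np.exp(steepness * (doy - end)))
    curve = up * down
    grid = np.arange(1.0, 367.0)
    peak = np.max(
        1.0 / (1.0 + np.exp(-steepness * (grid - start)))
        / (1.0 + np.exp(steepness * (grid - end)))
    )
    return curve / peak


def _timestamps(config: SiteSimConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.n_years - 1, month=12, day=31, hour=23, minute=30)
    return pd.date_range(start, end, freq="30min")


def _day_geometry(config: SiteSimConfig, ts: pd.DatetimeIndex):
    """Per-timestamp daylength (h), seasonal factor in [-1, 1], hour of day."""
    doy = ts.dayofyear.to_numpy(dtype=float)
    seasonal = np.sin(2.0 * np.pi * (doy - 80.0) / 365.25)
    daylen = 12.0 + 12.0 * config.latitude_proxy * seasonal
    hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    return daylen, seasonal, hour


def simulate_radiation(config: SiteSimConfig) -> pd.DataFrame:
    """Half-hourly global shortwave radiation Rg (W m⁻²).

    Clear-sky Rg follows a sinusoidal arc between sunrise and sunset; the
    noon amplitude scales seasonally from 10% (midwinter) to 100%
    (midsummer) of ``rg_max_summer``.  A day-level multiplicative clearness
    factor in (0, 1] (1 − clearness_noise × Beta(1.5, 4)) adds weather;
    ``clearness_noise=0`` disables it.  Rg is 0 at night.
    """
    config.validate()
    ts = _timestamps(config)
    daylen, seasonal, hour = _day_geometry(config, ts)
    sunrise = 12.0 - daylen / 2.0
    phase = (hour - sunrise) / daylen
    arc = np.where((phase > 0.0) & (phase < 1.0), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    amplitude = config.rg_max_summer * (0.55 + 0.45 * seasonal)

    day_index = pd.Series(ts.normalize())
    unique_days = day_index.unique()
    rng = _rng(config, "clearness")
    if config.clearness_noise > 0:
        clear_by_day = 1.0 - config.clearness_noise * rng.beta(1.5, 4.0, size=len(unique_days))
    else:
        clear_by_day = np.ones(len(unique_days))
    clearness = day_index.map(pd.Series(clear_by_day, index=unique_days)).to_numpy()

    rg = amplitude * arc * clearness
    return pd.DataFrame({"timestamp": ts, "rg": rg})


def _gap_mask(rng: np.random.Generator, n: int, fraction: float, block_mean: float = 12.0) -> np.ndarray:
    """Gap mask mixing geometric-length blocks (half the budget) with
    i.i.d. singletons, hitting the target count exactly."""
    mask = np.zeros(n, dtype=bool)
    target = int(round(fraction * n))
    if target == 0:
        return mask
    block_budget = target // 2
    while mask.sum() < block_budget:
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / block_mean))
        stop = min(start + length, n)
        mask[start:stop] = True
    free = np.flatnonzero(~mask)
    deficit = target - int(mask.sum())
    if deficit > 0:
        mask[rng.choice(free, size=min(deficit, free.size), replace=False)] = True
    elif deficit < 0:
        gap_idx = np.flatnonzero(mask)
        mask[rng.choice(gap_idx, size=-deficit, replace=False)] = False
    return mask


def simulate_site_fluxes(config: SiteSimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Half-hourly flux table (timestamp, gpp, rg, measured) plus truth.

    GPP = NRH(α(t), Amax(t), θ; PAR) + ε with α(t), Amax(t) following the
    double-logistic phenology (α floor 15%, Amax floor 5% of peak), Amax
    additionally scaled per year by a mean-one lognormal multiplier, and ε
    heteroscedastic with sd = ``noise_scale`` × modeled GPP.  A fraction
    ``gap_fraction`` of half-hours is flagged gap-filled (measured=False).
    """
    config.validate()
    rad = simulate_radiation(config)
    ts = pd.DatetimeIndex(rad["timestamp"])
    doy = ts.dayofyear.to_numpy(dtype=float)
    year = ts.year.to_numpy()
    phen = double_logistic(doy, config.season_start, config.season_end, config.season_steepness)

    years = np.arange(config.start_year, config.start_year + config.n_years)
    rng_year = _rng(config, "year_effects")
    if config.year_effect_sd > 0:
        s = config.year_effect_sd
        mult = np.exp(rng_year.normal(-0.5 * s * s, s, size=len(years)))
    else:
        mult = np.ones(len(years))
    year_multiplier = dict(zip((int(y) for y in years), (float(m) for m in mult)))
    ymult = pd.Series(year_multiplier).reindex(year).to_numpy()

    alpha_t = config.alpha_peak * (0.15 + 0.85 * phen)
    amax_t = config.amax_peak * ymult * (0.05 + 0.95 * phen)
    par = par_from_rg(rad["rg"].to_numpy())
    gpp_model = _nrh_vec(par, alpha_t, amax_t, config.theta_true)

    rng_noise = _rng(config, "flux_noise")
    if config.noise_scale > 0:
        sd = config.noise_scale * gpp_model
        if config.noise_kind == "gaussian":
            eps = rng_noise.normal(0.0, 1.0, size=gpp_model.size) * sd
        else:
            eps = rng_noise.laplace(0.0, 1.0, size=gpp_model.size) * sd / np.sqrt(2.0)
        gpp = gpp_model + eps
    else:
        gpp = gpp_model.copy()

    measured = ~_gap_mask(_rng(config, "gaps"), len(ts), config.gap_fraction)
    flux = pd.DataFrame(
        {"timestamp": ts, "gpp": gpp, "rg": rad["rg"].to_numpy(), "measured": measured}
    )

    dates = pd.date_range(ts[0].normalize(), ts[-1].normalize(), freq="D")
    d_doy = dates.dayofyear.to_numpy(dtype=float)
    d_phen = double_logistic(d_doy, config.season_start, config.season_end, config.season_steepness)
    d_mult = pd.Series(year_multiplier).reindex(dates.year.to_numpy()).to_numpy()
    truth = SyntheticTruth(
        site_id=config.site_id,
        dates=dates,
        alpha_daily=config.alpha_peak * (0.15 + 0.85 * d_phen),
        amax_daily=config.amax_peak * d_mult * (0.05 + 0.95 * d_phen),
        theta=config.theta_true,
        year_multiplier=year_multiplier,
        gppsat_by_year={
            y: float(nrh_gpp(QSAT_PAR, config.alpha_peak, config.amax_peak * m, config.theta_true))
            for y, m in year_multiplier.items()
        },
    )
    return flux, truth


def _nrh_vec(q: np.ndarray, alpha: np.ndarray, amax: np.ndarray, theta: float) -> np.ndarray:
    """NRH with elementwise α/Amax trajectories (generator fast path)."""
    if theta < 1e-9:
        aq = alpha * q
        return aq * amax / np.maximum(aq + amax, 1e-300)
    s = alpha * q + amax
    disc = np.maximum(s * s - 4.0 * theta * alpha * q * amax, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * theta)


def simulate_fapar_pixels(
    config: SiteSimConfig,
    n_neighbors: int = 4,
    neighbor_noise: float = 0.02,
    n_independent: int = 0,
    central_gap_fraction: float = 0.15,
    fapar_range: tuple[float, float] = (0.10, 0.85),
    beer_lambert_k: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """16-day FAPAR for a central pixel plus neighbors, and a LAI series.

    Correlated neighbors are the central seasonal course plus Gaussian noise
    of sd ``neighbor_noise`` (exact copies when 0); ``n_independent``
    additional neighbors are i.i.d. Beta(2, 2) — independent of the central
    pixel, to exercise the donor screen.  Gaps are injected into the central
    pixel only.  LAI follows from gapless central FAPAR by Beer–Lambert
    inversion LAI = −ln(1 − FAPAR)/k.

    Returns a long table (pixel_id, date, fapar, role) and the LAI series.
    """
    config.validate()
    if n_neighbors < 0 or n_independent < 0:
        raise ValueError("neighbor counts must be non-negative")
    if neighbor_noise < 0:
        raise ValueError("neighbor_noise must be non-negative")
    rng = _rng(config, "fapar")
    dates = pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.n_years - 1}-12-31",
        freq="16D",
    )
    phen = double_logistic(
        dates.dayofyear.to_numpy(dtype=float),
        config.season_start, config.season_end, config.season_steepness,
    )
    lo, hi = fapar_range
    central_true = np.clip(lo + (hi - lo) * phen, 0.0, 1.0)

    frames = []
    central_obs = central_true.copy()
    if central_gap_fraction > 0:
        n_gaps = int(round(central_gap_fraction * len(dates)))
        gap_idx = rng.choice(len(dates), size=n_gaps, replace=False)
        central_obs[gap_idx] = np.nan
    frames.append(pd.DataFrame(
        {"pixel_id": "central", "date": dates, "fapar": central_obs, "role": "central"}
    ))
    for j in range(n_neighbors):
        vals = np.clip(central_true + rng.normal(0.0, neighbor_noise, len(dates))
                       if neighbor_noise > 0 else central_true, 0.0, 1.0)
        frames.append(pd.DataFrame(
            {"pixel_id": f"nb{j:02d}", "date": dates, "fapar": vals, "role": "neighbor"}
        ))
    for j in range(n_independent):
        vals = rng.beta(2.0, 2.0, len(dates))
        frames.append(pd.DataFrame(
            {"pixel_id": f"ind{j:02d}", "date": dates, "fapar": vals, "role": "neighbor"}
        ))
    lai = pd.Series(
        -np.log(np.clip(1.0 - central_true, 1e-6, 1.0)) / beer_lambert_k,
        index=dates, name="lai",
    )
    return pd.concat(frames, ignore_index=True), lai


def simulate_trait_sites(
    n_sites: int = 20,
    slope: float = DEFAULT_TRAIT_SLOPE,
    intercept: float = DEFAULT_TRAIT_INTERCEPT,
    noise_sd: float = 3.0,
    seed: int = 0,
    npct_values=None,
    npct_range: tuple[float, float] = (1.2, 3.2),
    n_species_range: tuple[int, int] = (3, 8),
    species_npct_sd: float = 0.25,
    database_bias_sd: float = 0.2,
    p_coupling: str = "stoichiometric",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-site species trait tables plus per-site true GPPsat.

    Each site gets a community N% target (uniform over ``npct_range`` unless
    ``npct_values`` is given) and a true GPPsat =
    ``intercept + slope × N% + ε``, ε ~ N(0, ``noise_sd``).  Species N% is
    scattered around the target and re-centered so the abundance-weighted
    community mean matches it exactly; remaining traits are drawn with
    realistic ranges and configurable cross-correlations (C ≈ 470 mg g⁻¹,
    lognormal SLA, δ13C ≈ −28‰; P via an N:P ratio when
    ``p_coupling="stoichiometric"``, or drawn independently of N with
    ``p_coupling="independent"`` — the identifiable design for
    variable-selection recovery experiments).  A second "database" copy of every
    species row adds independent N% bias to mimic looking traits up in a
    global database instead of on site.

    Returns the species table (site, species, abundance, traits, source) and
    a site table (site, npct_true, gppsat_true).
    """
    if n_sites < 3:
        raise ValueError("n_sites must be >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if npct_values is None:
        npct = rng.uniform(*npct_range, size=n_sites)
    else:
        npct = np.asarray(npct_values, dtype=float)
        if npct.size != n_sites:
            raise ValueError("npct_values length must equal n_sites")
    eps = rng.normal(0.0, noise_sd, size=n_sites) if noise_sd > 0 else np.zeros(n_sites)
    gppsat_true = intercept + slope * npct + eps

    rows = []
    for i in range(n_sites):
        site = f"SYN-{i:03d}"
        n_sp = int(rng.integers(n_species_range[0], n_species_range[1] + 1))
        abund = rng.dirichlet(np.full(n_sp, 2.0))
        sp_npct = npct[i] + rng.normal(0.0, species_npct_sd, n_sp)
        sp_npct += npct[i] - float(np.sum(abund * sp_npct))  # pin CWM exactly
        sp_npct = np.maximum(sp_npct, 0.05)
        if p_coupling == "stoichiometric":
            np_ratio = rng.normal(14.0, 2.0, n_sp).clip(6.0, 25.0)
            p_mass = sp_npct * 10.0 / np_ratio
        elif p_coupling == "independent":
            # wide across-biome spread (~0.3–4 mg g⁻¹) uncorrelated with N
            p_mass = np.exp(rng.normal(np.log(1.3), 0.5, n_sp)).clip(0.2, 6.0)
        else:
            raise ValueError(f"unknown p_coupling {p_coupling!r}")
        c_mass = rng.normal(470.0, 25.0, n_sp).clip(350.0, 560.0)
        sla = np.exp(rng.normal(np.log(12.0), 0.3, n_sp)).clip(3.0, 35.0)
        d13c = rng.normal(-28.0, 1.5, n_sp)
        db_bias = rng.normal(0.0, database_bias_sd, n_sp)
        for j in range(n_sp):
            base = {
                "site": site,
                "species": f"sp{j:02d}",
                "abundance": abund[j],
                "p_mass": p_mass[j],
                "c_mass": c_mass[j],
                "sla": sla[j],
                "delta13c": d13c[j],
            }
            rows.append({**base, "n_mass": sp_npct[j] * 10.0, "source": "in_situ"})
            rows.append(
                {**base, "n_mass": max((sp_npct[j] + db_bias[j]) * 10.0, 0.5),
                 "source": "database"}
            )
    species = pd.DataFrame(rows)
    sites = pd.DataFrame(
        {"site": [f"SYN-{i:03d}" for i in range(n_sites)],
         "npct_true": npct, "gppsat_true": gppsat_true}
    )
    return species, sites


@dataclass
class SimulatedStudy:
    """A full synthetic multi-site study: inputs for every pipeline stage."""

    flux: dict[str, pd.DataFrame]
    fapar: dict[str, pd.DataFrame]
    lai: dict[str, pd.Series]
    species_traits: pd.DataFrame
    site_truth: pd.DataFrame
    truths: dict[str, SyntheticTruth]
    sampling_year: int
    configs: dict[str, SiteSimConfig] = field(default_factory=dict)


def _amax_for_gppsat(gppsat: float, alpha: float, theta: float, qsat: float = QSAT_PAR) -> float:
    """Invert the NRH at Qsat for Amax given target GPPsat."""
    aq = alpha * qsat
    if gppsat >= aq:
        raise ValueError("target GPPsat exceeds the light-limited bound αQsat")
    return gppsat * (aq - theta * gppsat) / (aq - gppsat)


def simulate_study(
    n_sites: int = 8,
    n_years: int = 3,
    seed: int = 0,
    start_year: int = 2005,
    noise_scale: float = 0.1,
    gap_fraction: float = 0.1,
    year_effect_sd: float = 0.05,
    trait_noise_sd: float = 3.0,
    base_config: SiteSimConfig | None = None,
) -> SimulatedStudy:
    """A coherent multi-site study linking fluxes, FAPAR and traits.

    Per-site community N% is drawn as in :func:`simulate_trait_sites`; the
    site's peak-season Amax is chosen so that true GPPsat at saturating PAR
    equals ``intercept + slope × N% + ε``.  Each site then gets its own flux
    record, FAPAR pixels and species trait tables (in-situ and database
    copies).  The trait-sampling year is the last simulated year.
    """
    base = base_config or SiteSimConfig()
    ss = np.random.SeedSequence(seed)
    site_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_sites)]
    species, site_truth = simulate_trait_sites(
        n_sites=n_sites, noise_sd=trait_noise_sd,
        seed=int(ss.generate_state(1)[0] % (2**31 - 1)),
    )
    flux, fapar_tabs, lai_tabs, truths, configs = {}, {}, {}, {}, {}
    for i, row in site_truth.iterrows():
        site = row["site"]
        amax_peak = _amax_for_gppsat(
            float(np.clip(row["gppsat_true"], 5.0, 0.9 * base.alpha_peak * QSAT_PAR)),
            base.alpha_peak, base.theta_true,
        )
        cfg = replace(
            base,
            site_id=site,
            n_years=n_years,
            start_year=start_year,
            amax_peak=amax_peak,
            noise_scale=noise_scale,
            gap_fraction=gap_fraction,
            year_effect_sd=year_effect_sd,
            seed=site_seeds[i],
        )
        flux[site], truths[site] = simulate_site_fluxes(cfg)
        fapar_tabs[site], lai_tabs[site] = simulate_fapar_pixels(cfg)
        configs[site] = cfg
    return SimulatedStudy(
        flux=flux, fapar=fapar_tabs, lai=lai_tabs,
        species_traits=species, site_truth=site_truth, truths=truths,
        sampling_year=start_year + n_years - 1, configs=configs,
    )
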