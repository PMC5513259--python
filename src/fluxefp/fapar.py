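"""FAPAR gap-filling, daily smoothing, and annual maximum LAI.

Satellite FAPAR arrives on a 16-day grid for a central pixel (the flux-tower
pixel) plus candidate neighbor pixels.  Gaps in the central series are filled
from neighbors whose association with the central pixel exceeds 0.75
(distance correlation by default, Pearson switchable), prioritized by
association strength, with a per-donor affine bias correction.  Residual
gaps fall back to a seasonal climatology across years, then to linear
interpolation — a deliberately simple stand-in for heavier spatiotemporal
fillers.  The gapless 16-day series is then smoothed to a daily series with
a cubic smoothing spline whose penalty is chosen by generalized
cross-validation, and clamped to [0, 1].

Annual maximum LAI is the 90th percentile of the year's 16-day retrievals.

All series are ``pandas.Series`` indexed by date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import pearsonr

from .stats import distance_correlation, percentile

__all__ = [
    "NEIGHBOR_CORR_MIN",
    "neighbor_screen",
    "gapfill_central",
    "fallback_fill",
    "smooth_to_daily",
    "annual_max_lai",
]

#: neighbors qualify as gap-fill donors only above this correlation (strict).
NEIGHBOR_CORR_MIN = 0.75
#: minimum shared non-missing 16-day steps for a neighbor to be considered.
MIN_SHARED_STEPS = 8


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "dcor":
        return distance_correlation(x, y)
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def neighbor_screen(
    central: pd.Series,
    neighbors: dict[str, pd.Series],
    threshold: float = NEIGHBOR_CORR_MIN,
    method: str = "dcor",
) -> list[tuple[str, float]]:
    """Rank neighbor pixels usable as gap-fill donors.

    Correlation is computed on pairwise-complete 16-day steps; candidates
    with fewer than 8 shared steps, constant overlap, or correlation not
    strictly above ``threshold`` are dropped.  Returns ``(pixel_id, corr)``
    sorted by descending correlation.

    Raises
    ------
    ValueError
        If the central series is entirely missing.
    """
    if central.dropna().empty:
        raise ValueError("central FAPAR series is entirely missing")
    ranked: list[tuple[str, float]] = []
    for pid, series in neighbors.items():
        pair = pd.concat({"c": central, "n": series}, axis=1, join="inner").dropna()
        if len(pair) < MIN_SHARED_STEPS:
            continue
        try:
            c = _corr(pair["c"].to_numpy(), pair["n"].to_numpy(), method)
        except ValueError:  # constant overlap
            continue
        if c > threshold:
            ranked.append((pid, c))
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


def gapfill_central(
    central: pd.Series,
    ranked_donors: list[tuple[str, float]],
    neighbors: dict[str, pd.Series],
    affine_correction: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Fill central-pixel gaps from ranked donor pixels.

    Each gap takes the value of the highest-ranked donor that has one at
    that date.  With ``affine_correction`` (default) the donor series is
    first mapped through an OLS regression of the central pixel on the donor
    over their shared dates (1-km neighbors can differ in level); without
    it, raw substitution.  Values are clamped to [0, 1].  Non-missing
    central values are never altered.

    Returns the filled series and a provenance series ("observed", the donor
    pixel id, or "unfilled").
    """
    filled = central.copy()
    provenance = pd.Series(
        np.where(central.notna(), "observed", "unfilled"), index=central.index
    )
    for pid, _ in ranked_donors:
        donor = neighbors[pid]
        gaps = filled.index[filled.isna()]
        if len(gaps) == 0:
            break
        if affine_correction:
            shared = pd.concat({"c": central, "d": donor}, axis=1, join="inner").dropna()
            if len(shared) >= 2 and shared["d"].nunique() > 1:
                slope, intercept = np.polyfit(shared["d"], shared["c"], 1)
            else:
                slope, intercept = 1.0, 0.0
        else:
            slope, intercept = 1.0, 0.0
        avail = donor.reindex(gaps).dropna()
        if avail.empty:
            continue
        filled.loc[avail.index] = np.clip(intercept + slope * avail.to_numpy(), 0.0, 1.0)
        provenance.loc[avail.index] = pid
    return filled, provenance


def fallback_fill(series: pd.Series) -> pd.Series:
    """Fill residual gaps by multi-year seasonal climatology, then linear
    interpolation in time; clamp to [0, 1].

    A gap at a given position in the seasonal cycle takes the mean of values
    at the same day-of-year (±8 days, half the 16-day step) in other years
    when any exist; remaining gaps are linearly interpolated (edges filled
    nearest).  The result has no missing values.

    Raises
    ------
    ValueError
        If the series has no non-missing values at all.
    """
    if series.dropna().empty:
        raise ValueError("cannot fill a series with no observed values")
    out = series.copy()
    idx = pd.to_datetime(out.index)
    doy = idx.dayofyear.to_numpy()
    year = idx.year.to_numpy()
    vals = out.to_numpy(dtype=float)
    for i in np.flatnonzero(np.isnan(vals)):
        # circular day-of-year distance to tolerate year-boundary wraps
        delta = np.abs(doy - doy[i])
        delta = np.minimum(delta, 365 - delta)
        same_season = (delta <= 8) & (year != year[i]) & ~np.isnan(vals)
        if same_season.any():
            out.iloc[i] = float(np.mean(vals[same_season]))
    out = out.interpolate(method="linear", limit_direction="both")
    return out.clip(0.0, 1.0)


def smooth_to_daily(series: pd.Series, lam: float | None = None) -> pd.Series:
    """Smooth a gapless 16-day FAPAR series to daily resolution.

    Cubic smoothing spline with penalty chosen by generalized
    cross-validation (``lam=None``), evaluated on every calendar day spanned
    by the series, clamped to [0, 1].

    Raises
    ------
    ValueError
        If the series has gaps or fewer than 4 points.
    """
    if series.isna().any():
        raise ValueError("smooth_to_daily requires a gapless series")
    if len(series) < 4:
        raise ValueError("smoothing spline needs at least 4 knots")
    idx = pd.to_datetime(series.index)
    t0 = idx[0]
    x = (idx - t0).days.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        # GCV is ill-posed for an exactly constant series; the answer is exact
        days = pd.date_range(idx[0], idx[-1], freq="D")
        return pd.Series(np.full(len(days), y[0]), index=days, name="fapar_daily")
    spline = make_smoothing_spline(x, y, lam=lam)
    days = pd.date_range(idx[0], idx[-1], freq="D")
    xd = (days - t0).days.to_numpy(dtype=float)
    return pd.Series(np.clip(spline(xd), 0.0, 1.0), index=days, name="fapar_daily")


def annual_max_lai(lai: pd.Series, year: int, min_values: int = 5) -> float:
    """Annual maximum LAI as the 90th percentile of the year's retrievals.

    Raises
    ------
    ValueError
        If fewer than ``min_values`` non-missing retrievals exist in the
        year, or any LAI is negative.
    """
    idx = pd.to_datetime(lai.index)
    vals = lai.loc[idx.year == year].dropna()
    if (vals < 0).any():
        raise ValueError("LAI must be non-negative")
    if len(vals) < min_values:
        raise ValueError(
            f"annual_max_lai needs >= {min_values} retrievals in {year}, got {len(vals)}"
        )
    return percentile(vals.to_numpy(), 90.0)
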