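"""Half-hourly flux quality control and radiation conversion.

The screening pipeline applied to each site-year of half-hourly GPP:

1. convert global shortwave radiation Rg (W m⁻²) to PAR via the factor 2.11;
2. keep only daytime (Rg > 10 W m⁻², strict) and measured (not gap-filled)
   half hours;
3. flag April–September days whose gap fraction exceeds 80% and drop
   site-years where more than 25% of those 183 days are bad.

All "more than" thresholds are strict inequalities.  A day is judged against
the full complement of 48 half-hours; missing records count as gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PAR_PER_RG",
    "RG_DAYTIME_MIN",
    "DAY_GAP_MAX",
    "YEAR_BAD_DAY_MAX",
    "SiteYearScreenResult",
    "par_from_rg",
    "filter_daytime_measured",
    "screen_site_year",
    "compute_apar",
]

#: μmol photons m⁻² s⁻¹ of PAR per W m⁻² of global shortwave radiation.
PAR_PER_RG = 2.11
#: daytime threshold on Rg (W m⁻², strict).
RG_DAYTIME_MIN = 10.0
#: a day is "bad" if its half-hourly gap fraction strictly exceeds this.
DAY_GAP_MAX = 0.80
#: a site-year is excluded if its bad-day fraction strictly exceeds this.
YEAR_BAD_DAY_MAX = 0.25

_HALF_HOURS_PER_DAY = 48


@dataclass(frozen=True)
class SiteYearScreenResult:
    """Gap screening verdict for one site-year (April–September)."""

    site: str
    year: int
    n_days_screened: int
    n_bad_days: int
    bad_fraction: float
    keep: bool
    status: str = "ok"  # "ok" | "empty"


def par_from_rg(rg):
    """PAR (μmol m⁻² s⁻¹) from global shortwave radiation Rg (W m⁻²).

    Linear conversion PAR = 2.11 × Rg; NaN propagates.

    Raises
    ------
    ValueError
        If any finite value of ``rg`` is negative.
    """
    arr = np.asarray(rg, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("Rg must be non-negative")
    out = PAR_PER_RG * arr
    return float(out) if np.isscalar(rg) else out


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"flux table missing required column(s): {missing}")


def filter_daytime_measured(
    records: pd.DataFrame,
    rg_daytime_min: float = RG_DAYTIME_MIN,
) -> pd.DataFrame:
    """Keep only daytime (rg strictly > threshold) measured half-hours.

    Order is preserved; the operation is idempotent.  A record at exactly
    the threshold (Rg = 10 W m⁻²) is removed.
    """
    _require_columns(records, ("rg", "measured"))
    mask = (records["rg"] > rg_daytime_min) & records["measured"].astype(bool)
    mask &= records["gpp"].notna() if "gpp" in records.columns else True
    return records.loc[mask]


def screen_site_year(
    records: pd.DataFrame,
    year: int,
    site: str = "",
    day_gap_max: float = DAY_GAP_MAX,
    year_bad_day_max: float = YEAR_BAD_DAY_MAX,
) -> SiteYearScreenResult:
    """Screen one site-year on April–September half-hourly gap structure.

    Every calendar day from Apr 1 to Sep 30 (183 days) is screened; a day
    with no records at all counts as fully gapped.  ``records`` needs
    ``timestamp`` and ``measured`` columns and may span several years.
    """
    _require_columns(records, ("timestamp", "measured"))
    ts = pd.to_datetime(records["timestamp"])
    in_window = (ts.dt.year == year) & (ts.dt.month >= 4) & (ts.dt.month <= 9)
    days = pd.date_range(f"{year}-04-01", f"{year}-09-30", freq="D")
    n_days = len(days)

    sub = records.loc[in_window]
    if sub.empty:
        return SiteYearScreenResult(site, year, n_days, n_days, 1.0, False, "empty")

    measured_per_day = (
        sub.loc[sub["measured"].astype(bool), "timestamp"]
        .pipe(pd.to_datetime)
        .dt.normalize()
        .value_counts()
        .reindex(days, fill_value=0)
    )
    gap_fraction = 1.0 - measured_per_day.clip(upper=_HALF_HOURS_PER_DAY) / _HALF_HOURS_PER_DAY
    n_bad = int((gap_fraction > day_gap_max).sum())
    bad_fraction = n_bad / n_days
    return SiteYearScreenResult(
        site, year, n_days, n_bad, bad_fraction, keep=bad_fraction <= year_bad_day_max
    )


def compute_apar(records: pd.DataFrame, daily_fapar: pd.Series) -> pd.DataFrame:
    """Attach APAR = FAPAR(day) × PAR to half-hourly records.

    ``daily_fapar`` is indexed by (normalized) date.  Dates without FAPAR
    yield missing APAR (NaN), never zero.  Adds a ``par`` column if absent.
    """
    _require_columns(records, ("timestamp", "rg"))
    out = records.copy()
    if "par" not in out.columns:
        out["par"] = par_from_rg(out["rg"].to_numpy())
    day = pd.to_datetime(out["timestamp"]).dt.normalize()
    fapar = day.map(daily_fapar)
    out["apar"] = fapar.to_numpy(dtype=float) * out["par"].to_numpy(dtype=float)
    return out
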