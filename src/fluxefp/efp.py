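"""Annual ecosystem-functional-property extraction and estimator comparison.

Daily capacity series (Amax, GPPsat, GPPcum and their APAR-driven
".structure" variants) are reduced to one value per site-year by taking the
maximum or a percentile (90th–60th) over the retained (R² > 0.6) days.
Interannual variability (IAV) per site is the coefficient of variation of
the annual values; estimators and extraction percentiles are compared by
the distribution of CV across sites with at least 5 years of data — the
extraction minimizing mean CV is the most robust capacity estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import percentile

__all__ = [
    "ESTIMATORS",
    "PERCENTILE_CHOICES",
    "SiteIAV",
    "annual_extract",
    "annual_table",
    "iav_cv",
    "compare_estimators",
    "select_site_efp",
]

#: the six capacity estimators (".structure" = APAR-driven).
ESTIMATORS = (
    "Amax", "Amax.structure",
    "GPPsat", "GPPsat.structure",
    "GPPcum", "GPPcum.structure",
)
#: annual extraction choices: the maximum and percentiles 90th–60th.
PERCENTILE_CHOICES = ("max", 90, 85, 80, 75, 70, 60)

_COLUMN_OF = {"Amax": "amax", "GPPsat": "gpp_sat", "GPPcum": "gpp_cum"}


@dataclass(frozen=True)
class SiteIAV:
    """Interannual variability of one estimator/percentile at one site."""

    site: str
    estimator: str
    percentile: str
    n_years: int
    cv: float


def _pct_label(p) -> str:
    return "max" if p == "max" else str(int(p))


def annual_extract(
    daily: pd.DataFrame,
    year: int,
    pct="max",
    value_col: str = "gpp_sat",
    min_days: int = 10,
) -> float:
    """One annual value from a daily capacity series.

    Only retained days (fit R² above threshold) in the calendar year count.
    ``pct`` is ``"max"`` or a percentile (linear-interpolation convention).
    Returns NaN when fewer than ``min_days`` retained days are available.
    """
    dates = pd.to_datetime(daily["center_date"])
    mask = (dates.dt.year == year) & daily["retained"].astype(bool)
    vals = daily.loc[mask, value_col].dropna().to_numpy(dtype=float)
    if vals.size < min_days:
        return float("nan")
    if pct == "max":
        return float(vals.max())
    return percentile(vals, float(pct))


def annual_table(
    daily_by_kind: dict[str, pd.DataFrame],
    site: str,
    percentiles=PERCENTILE_CHOICES,
    min_days: int = 10,
) -> pd.DataFrame:
    """All (estimator × percentile × year) annual values for one site.

    ``daily_by_kind`` maps radiation kind ("PAR"/"APAR") to the daily table
    from :func:`fluxefp.lightresponse.fit_site`.
    """
    rows = []
    for kind, daily in daily_by_kind.items():
        suffix = "" if kind == "PAR" else ".structure"
        years = sorted(pd.to_datetime(daily["center_date"]).dt.year.unique())
        for base, col in _COLUMN_OF.items():
            for year in years:
                for p in percentiles:
                    value = annual_extract(daily, year, p, value_col=col, min_days=min_days)
                    rows.append(
                        {
                            "site": site,
                            "year": int(year),
                            "estimator": base + suffix,
                            "percentile": _pct_label(p),
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def iav_cv(values) -> float:
    """Coefficient of variation across years: sample sd (n−1) over mean.

    Raises
    ------
    ValueError
        With fewer than 2 years or non-positive mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("CV needs at least 2 annual values")
    m = float(v.mean())
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / m)


def compare_estimators(annual: pd.DataFrame, min_years: int = 5) -> pd.DataFrame:
    """Compare estimators × extraction percentiles by cross-site CV spread.

    ``annual`` is the long table (site, year, estimator, percentile, value).
    Sites contribute only where they have at least ``min_years`` non-missing
    annual values.  Returns one row per estimator × percentile with the
    mean, quartiles and range of CV across sites, the number of sites, and
    a flag on the percentile that minimizes mean CV within each estimator.

    Raises
    ------
    ValueError
        If no site qualifies anywhere.
    """
    rows = []
    for (est, pct), grp in annual.groupby(["estimator", "percentile"], sort=True):
        cvs = []
        for _, sgrp in grp.groupby("site"):
            vals = sgrp["value"].dropna()
            if len(vals) >= min_years:
                cvs.append(iav_cv(vals.to_numpy()))
        if not cvs:
            continue
        cvs = np.asarray(cvs)
        rows.append(
            {
                "estimator": est,
                "percentile": pct,
                "n_sites": cvs.size,
                "cv_mean": float(cvs.mean()),
                "cv_q25": percentile(cvs, 25.0),
                "cv_q75": percentile(cvs, 75.0),
                "cv_min": float(cvs.min()),
                "cv_max": float(cvs.max()),
            }
        )
    if not rows:
        raise ValueError(f"no site has >= {min_years} years for any estimator")
    out = pd.DataFrame(rows)
    out["best_percentile"] = False
    for est, grp in out.groupby("estimator"):
        out.loc[grp["cv_mean"].idxmin(), "best_percentile"] = True
    return out.sort_values(["estimator", "percentile"]).reset_index(drop=True)


def select_site_efp(
    annual_values: pd.Series,
    policy: str = "multiyear_mean",
    specific_year: int | None = None,
) -> float:
    """Per-site capacity scalar used for trait linking.

    ``annual_values`` is indexed by year.  Policy ``multiyear_mean`` returns
    the mean over available years; ``specific_year`` returns that year's
    value (NaN if that year is absent — e.g. the trait-sampling year).
    """
    vals = annual_values.dropna()
    if policy == "multiyear_mean":
        return float(vals.mean()) if len(vals) else float("nan")
    if policy == "specific_year":
        if specific_year is None:
            raise ValueError("specific_year policy requires a year")
        return float(vals.get(specific_year, float("nan")))
    raise ValueError(f"unknown policy {policy!r}")
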