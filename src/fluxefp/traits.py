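"""Community-weighted mean leaf traits and derived stoichiometry.

Species-level trait measurements (leaf N, P, C per dry mass, SLA, δ13C) are
aggregated to site level as abundance-weighted means (CWM).  Within-species
replicates are averaged to a species value first.  Per-area nutrient
contents follow from mass-based contents and SLA; with n_mass in mg g⁻¹ and
SLA in mm² mg⁻¹ the ratio n_mass/SLA is already in g m⁻².  Leaf C/N is the
mass ratio c_mass/n_mass (g/g).  N% (leaf N per 100 g dry mass) is
n_mass/10.

Trait tables carry columns: site, species, abundance, n_mass, p_mass,
c_mass, sla, delta13c, optional n_area/p_area, source (in_situ | database).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_COLUMNS",
    "cwm",
    "derive_stoichiometry",
    "site_species_mean",
    "community_traits",
]

TRAIT_COLUMNS = ("n_mass", "p_mass", "c_mass", "sla", "delta13c", "n_area", "p_area", "cn")


def cwm(values, abundances) -> float:
    """Community-weighted mean Σ aᵢ vᵢ.

    Species with missing values are dropped and the remaining abundances
    renormalized to sum to 1.  Returns NaN when every value is missing.

    Raises
    ------
    ValueError
        On length mismatch, negative abundances, or abundances that do not
        sum to 1 (before dropping missing values) within 1e-6.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if v.shape != a.shape:
        raise ValueError("values and abundances must have equal length")
    if np.any(a < 0) or np.isnan(a).any():
        raise ValueError("abundances must be non-negative and non-missing")
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {a.sum():.6f}, expected 1")
    ok = ~np.isnan(v)
    if not ok.any():
        return float("nan")
    a_ok = a[ok]
    if a_ok.sum() == 0.0:
        return float("nan")
    return float(np.sum(v[ok] * a_ok / a_ok.sum()))


def derive_stoichiometry(records: pd.DataFrame, conflict_tol: float = 0.05) -> pd.DataFrame:
    """Add C/N (g/g) and per-area nutrient contents to a trait table.

    ``cn = c_mass / n_mass`` (missing where n_mass is 0 or missing);
    ``n_area = n_mass / sla`` in g m⁻² (likewise p_area).  Where a provided
    per-area value disagrees with the derived one by more than
    ``conflict_tol`` (relative), the provided value is kept and a warning
    issued.
    """
    out = records.copy()
    n = out["n_mass"].to_numpy(dtype=float)
    c = out["c_mass"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.where(n > 0, c / n, np.nan)
    out["cn"] = cn
    sla = out["sla"].to_numpy(dtype=float)
    for mass_col, area_col in (("n_mass", "n_area"), ("p_mass", "p_area")):
        with np.errstate(divide="ignore", invalid="ignore"):
            derived = np.where(sla > 0, out[mass_col].to_numpy(dtype=float) / sla, np.nan)
        if area_col in out.columns:
            provided = out[area_col].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(provided - derived) / np.abs(derived)
            conflict = (~np.isnan(provided)) & (~np.isnan(derived)) & (rel > conflict_tol)
            if conflict.any():
                warnings.warn(
                    f"{conflict.sum()} provided {area_col} value(s) deviate >"
                    f"{conflict_tol:.0%} from n_mass/SLA-derived; keeping provided",
                    stacklevel=2,
                )
            out[area_col] = np.where(np.isnan(provided), derived, provided)
        else:
            out[area_col] = derived
    return out


def _species_means(site_records: pd.DataFrame) -> pd.DataFrame:
    """Average within-species replicates to one row per species."""
    trait_cols = [c for c in TRAIT_COLUMNS if c in site_records.columns]
    agg = {c: "mean" for c in trait_cols}
    agg["abundance"] = "first"
    return site_records.groupby("species", sort=True).agg(agg).reset_index()


def site_species_mean(site_records: pd.DataFrame, weighting: str = "abundance") -> dict:
    """Site-level trait vector from one site's species records.

    ``weighting="abundance"`` gives the CWM; ``"unweighted"`` the simple
    mean across species (the abundance-uncertainty sensitivity variant).
    """
    if weighting not in ("abundance", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    sp = _species_means(site_records)
    if len(sp) == 0:
        raise ValueError("site has no species records")
    a = sp["abundance"].to_numpy(dtype=float)
    if weighting == "unweighted":
        a = np.full(len(sp), 1.0 / len(sp))
    out = {}
    for col in (c for c in TRAIT_COLUMNS if c in sp.columns):
        out[col] = cwm(sp[col].to_numpy(dtype=float), a)
    if "n_mass" in out:
        out["n_pct"] = out["n_mass"] / 10.0  # mg g⁻¹ → g per 100 g
    return out


def community_traits(
    records: pd.DataFrame,
    weighting: str = "abundance",
    derive: bool = True,
) -> pd.DataFrame:
    """Per-site community trait table from a species-level trait table.

    Derives stoichiometric traits first (unless ``derive=False``), then
    aggregates per site.  Returns one row per site (and per ``source`` value
    if present) with CWM traits and N%.
    """
    df = derive_stoichiometry(records) if derive else records.copy()
    keys = ["site", "source"] if "source" in df.columns else ["site"]
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        row.update(site_species_mean(grp, weighting=weighting))
        rows.append(row)
    return pd.DataFrame(rows)
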