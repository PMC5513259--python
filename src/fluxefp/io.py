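"""CSV dialects, pipeline configuration and the run manifest.

All inputs and outputs are plain CSV with documented columns (the original
flux-network distributions are access-restricted, so the package defines
open dialects):

* flux:   ``timestamp`` (ISO 8601, half-hourly), ``gpp``, ``rg``,
          ``measured`` (0/1; 0 = gap-filled);
* FAPAR:  ``pixel_id``, ``date``, ``fapar``, ``role`` (central|neighbor),
          optional ``lai`` on central rows;
* traits: ``site``, ``species``, ``abundance``, ``n_mass``, ``p_mass``,
          ``c_mass``, ``sla``, ``delta13c``, optional ``n_area``/``p_area``,
          ``source`` (in_situ|database).

The sentinel ``-9999`` reads as missing.  ``PipelineConfig`` gathers every
numeric threshold the pipeline applies, so no stage hides a constant; the
manifest records a hash of the configuration along with per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = ["MISSING_SENTINEL", "PipelineConfig", "RunManifest",
           "read_flux_csv", "read_fapar_csv", "read_trait_csv"]

MISSING_SENTINEL = -9999.0


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one place."""

    # --- QC thresholds ---
    rg_daytime_min: float = 10.0  # W m⁻², strict
    day_gap_max: float = 0.80
    year_bad_day_max: float = 0.25
    # --- light-response fitting ---
    window_half_width: int = 2  # days; 5-day window
    window_step: int = 1  # days between center dates
    min_window_points: int = 20
    n_starts: int = 5
    r2_threshold: float = 0.6
    qsat_par: float = 2110.0
    qsat_apar: float = 2000.0
    # --- annual extraction / IAV ---
    percentile: float = 90.0
    percentiles_compared: tuple = ("max", 90, 85, 80, 75, 70, 60)
    min_retained_days: int = 10
    min_years: int = 5
    # --- FAPAR ---
    neighbor_corr_min: float = 0.75
    neighbor_corr_method: str = "dcor"
    # --- exclusions (site metadata, not inferred) ---
    exclude_sites: tuple = ()
    exclude_site_years: tuple = ()  # of "SITE:YEAR"
    # --- synthetic study (simulate=True) ---
    simulate: bool = True
    n_sites: int = 6
    n_years: int = 3
    seed: int = 0
    noise_scale: float = 0.1
    gap_fraction: float = 0.1
    year_effect_sd: float = 0.05
    trait_noise_sd: float = 3.0
    # --- linking ---
    estimator: str = "GPPsat"
    resampling_B: int = 499
    # --- input paths (simulate=False) ---
    flux_paths: dict = field(default_factory=dict)  # site -> csv path
    fapar_paths: dict = field(default_factory=dict)
    trait_path: str = ""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key in ("percentiles_compared", "exclude_sites", "exclude_site_years"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    software_version: str
    started: str
    finished: str = ""
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _replace_sentinel(df: pd.DataFrame, cols) -> pd.DataFrame:
    for c in cols:
        if c in df.columns:
            df[c] = df[c].replace(MISSING_SENTINEL, np.nan)
    return df


def read_flux_csv(path) -> pd.DataFrame:
    """Read a half-hourly flux CSV.

    Validates mandatory columns, ISO timestamps, uniqueness; converts the
    -9999 sentinel to missing and ``measured`` to boolean.  Attaches the
    count of irregular (non-30-min) steps as ``df.attrs["irregular_steps"]``.

    Raises
    ------
    ValueError
        Naming any missing mandatory column or duplicated timestamp.
    """
    df = pd.read_csv(path)
    required = ["timestamp", "gpp", "rg", "measured"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"flux CSV {path}: missing mandatory column(s) {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    dup = df["timestamp"][df["timestamp"].duplicated()]
    if not dup.empty:
        raise ValueError(f"flux CSV {path}: duplicated timestamp {dup.iloc[0]}")
    df = _replace_sentinel(df, ("gpp", "rg"))
    df["measured"] = df["measured"].astype(float).astype(bool)
    steps = df["timestamp"].diff().dropna()
    df.attrs["irregular_steps"] = int((steps != pd.Timedelta(minutes=30)).sum())
    return df


def read_fapar_csv(path) -> pd.DataFrame:
    """Read a 16-day FAPAR pixel table (pixel_id, date, fapar, role[, lai])."""
    df = pd.read_csv(path)
    required = ["pixel_id", "date", "fapar", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"FAPAR CSV {path}: missing mandatory column(s) {missing}")
    df["date"] = pd.to_datetime(df["date"])
    df = _replace_sentinel(df, ("fapar", "lai"))
    bad = df["fapar"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError(f"FAPAR CSV {path}: values outside [0, 1]")
    return df


def read_trait_csv(path) -> pd.DataFrame:
    """Read a species-level trait table."""
    df = pd.read_csv(path)
    required = ["site", "species", "abundance", "n_mass"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trait CSV {path}: missing mandatory column(s) {missing}")
    numeric = [c for c in df.columns if c not in ("site", "species", "source")]
    return _replace_sentinel(df, numeric)
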