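"""Pipeline runner: QC → FAPAR → light-response fits → annual EFPs →
community traits → trait linking.

Outputs are plain CSV/JSON written with a fixed float format, so a rerun
with the same configuration and seed is byte-identical (the manifest, which
carries wall-clock timestamps, is the one exception).
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .efp import annual_table, compare_estimators
from .fapar import annual_max_lai, fallback_fill, gapfill_central, neighbor_screen, smooth_to_daily
from .io import PipelineConfig, RunManifest, read_fapar_csv, read_flux_csv, read_trait_csv
from .lightresponse import fit_site
from .linking import ancova, expand_predictors, run_scenarios, scenario_points, stepwise_aic, year_resampling_test
from .qc import compute_apar, filter_daytime_measured, screen_site_year
from .synthetic import simulate_study
from .traits import community_traits

__all__ = ["PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _json_write(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        study = simulate_study(
            n_sites=config.n_sites, n_years=config.n_years, seed=config.seed,
            noise_scale=config.noise_scale, gap_fraction=config.gap_fraction,
            year_effect_sd=config.year_effect_sd, trait_noise_sd=config.trait_noise_sd,
        )
        return study.flux, study.fapar, study.lai, study.species_traits, study.sampling_year
    flux = {site: read_flux_csv(p) for site, p in config.flux_paths.items()}
    fapar, lai = {}, {}
    for site, p in config.fapar_paths.items():
        tab = read_fapar_csv(p)
        fapar[site] = tab
        central = tab.loc[tab["role"] == "central"]
        if "lai" in tab.columns:
            lai[site] = central.set_index("date")["lai"]
    species = read_trait_csv(config.trait_path)
    years = [pd.to_datetime(f["timestamp"]).dt.year.max() for f in flux.values()]
    return flux, fapar, lai, species, int(max(years))


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute all stages and write outputs under ``outdir``.

    Raises :class:`PipelineError` naming the failing stage; a manifest of
    completed stages is still written in that case.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        software_version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    _json_write(config.to_dict(), outdir / "config.json")
    try:
        flux, fapar_tabs, lai_tabs, species, sampling_year = _load_inputs(config)
        flux = {s: f for s, f in flux.items() if s not in set(config.exclude_sites)}
        manifest.stage_counts["input_sites"] = len(flux)

        # ---- stage: QC -------------------------------------------------
        excluded = {
            (s, int(y)) for s, y in
            (e.split(":") for e in config.exclude_site_years)
        } if config.exclude_site_years else set()
        screen_rows, filtered = [], {}
        kept_years: dict[str, list[int]] = {}
        for site, records in flux.items():
            years = sorted(pd.to_datetime(records["timestamp"]).dt.year.unique())
            keep = []
            for year in years:
                res = screen_site_year(
                    records, int(year), site=site,
                    day_gap_max=config.day_gap_max,
                    year_bad_day_max=config.year_bad_day_max,
                )
                ok = res.keep and (site, int(year)) not in excluded
                screen_rows.append(
                    {"site": site, "year": int(year), "n_bad_days": res.n_bad_days,
                     "bad_fraction": res.bad_fraction, "keep": ok, "status": res.status}
                )
                if ok:
                    keep.append(int(year))
            kept_years[site] = keep
            sub = records.loc[pd.to_datetime(records["timestamp"]).dt.year.isin(keep)]
            filtered[site] = filter_daytime_measured(sub, config.rg_daytime_min)
        _write(pd.DataFrame(screen_rows), outdir / "screening.csv")
        filtered = {s: df for s, df in filtered.items() if len(df)}
        if not filtered or not any(kept_years.values()):
            raise PipelineError("qc", "no qualifying site-years after screening")
        manifest.stage_counts["qc_half_hours"] = int(sum(len(d) for d in filtered.values()))

        # ---- stage: FAPAR ----------------------------------------------
        daily_fapar, lai_sampling = {}, {}
        fapar_rows = []
        for site, tab in fapar_tabs.items():
            if site not in filtered:
                continue
            central = tab.loc[tab["role"] == "central"].set_index("date")["fapar"]
            neighbors = {
                pid: grp.set_index("date")["fapar"]
                for pid, grp in tab.loc[tab["role"] == "neighbor"].groupby("pixel_id")
            }
            ranked = neighbor_screen(
                central, neighbors,
                threshold=config.neighbor_corr_min, method=config.neighbor_corr_method,
            )
            filled, _prov = gapfill_central(central, ranked, neighbors)
            filled = fallback_fill(filled)
            daily = smooth_to_daily(filled)
            daily_fapar[site] = daily
            fapar_rows.append(pd.DataFrame(
                {"site": site, "date": daily.index, "fapar_daily": daily.to_numpy()}
            ))
            if site in lai_tabs:
                try:
                    lai_sampling[site] = annual_max_lai(lai_tabs[site], sampling_year)
                except ValueError:
                    pass
            filtered[site] = compute_apar(filtered[site], daily)
        _write(pd.concat(fapar_rows, ignore_index=True), outdir / "fapar_daily.csv")
        manifest.stage_counts["fapar_sites"] = len(daily_fapar)

        # ---- stage: light-response fitting ------------------------------
        daily_frames = []
        daily_by_site: dict[str, dict[str, pd.DataFrame]] = {}
        for site, records in filtered.items():
            daily_by_site[site] = {}
            for kind in ("PAR", "APAR"):
                daily = fit_site(
                    records, kind,
                    step_days=config.window_step,
                    r2_threshold=config.r2_threshold,
                    half_width_days=config.window_half_width,
                    min_points=config.min_window_points,
                    n_starts=config.n_starts,
                )
                daily_by_site[site][kind] = daily
                daily_frames.append(daily.assign(site=site))
        all_daily = pd.concat(daily_frames, ignore_index=True)
        _write(all_daily, outdir / "daily_efp.csv")
        manifest.stage_counts["window_fits"] = int(len(all_daily))
        manifest.stage_counts["retained_days"] = int(all_daily["retained"].sum())

        # ---- stage: annual EFP extraction and IAV ------------------------
        annual = pd.concat(
            [
                annual_table(kinds, site, percentiles=config.percentiles_compared,
                             min_days=config.min_retained_days)
                for site, kinds in daily_by_site.items()
            ],
            ignore_index=True,
        )
        _write(annual, outdir / "annual_efp.csv")
        try:
            comparison = compare_estimators(annual, min_years=config.min_years)
            _write(comparison, outdir / "iav_comparison.csv")
        except ValueError as exc:
            manifest.warnings.append(f"iav comparison skipped: {exc}")
        manifest.stage_counts["annual_values"] = int(annual["value"].notna().sum())

        # ---- stage: community traits -------------------------------------
        community = community_traits(species)
        if "lai" not in community.columns and lai_sampling:
            community["lai"] = community["site"].map(lai_sampling)
        _write(community, outdir / "community_traits.csv")
        manifest.stage_counts["trait_sites"] = int(community["site"].nunique())

        # ---- stage: linking ----------------------------------------------
        sel = annual.loc[
            (annual["estimator"] == config.estimator)
            & (annual["percentile"] == str(int(config.percentile)))
        , ["site", "year", "value"]]
        sampling_map = {s: sampling_year for s in sel["site"].unique()}
        scen = run_scenarios(sel, community, sampling_map)
        _write(scen, outdir / "scenarios.csv")

        pts = scenario_points(sel, community, sampling_map)
        linking_json: dict = {}
        try:
            anc = ancova(pts["efp"], pts["trait"], pts["scenario"])
            linking_json["ancova"] = {
                "interaction_f": anc.interaction_f, "interaction_p": anc.interaction_p,
                "group_f": anc.group_f, "group_p": anc.group_p,
                "n_groups": anc.n_groups, "n": anc.n,
            }
        except ValueError as exc:
            manifest.warnings.append(f"ancova skipped: {exc}")

        insitu = community.loc[community["source"] == "in_situ"].set_index("site")
        try:
            resamp = year_resampling_test(
                sel, insitu["n_pct"], sampling_map,
                B=config.resampling_B, seed=config.seed,
            )
            linking_json["year_resampling"] = {
                "observed_r2": resamp["observed_r2"], "p_value": resamp["p_value"],
                "n_sites": resamp["n_sites"], "B": config.resampling_B,
                "null_r2_mean": float(np.mean(resamp["null_r2"])),
            }
        except ValueError as exc:
            manifest.warnings.append(f"year resampling skipped: {exc}")

        # stepwise trait selection on time-space synchronized capacity
        sync = pts.loc[pts["scenario"] == "sampling_year|in_situ"].set_index("site")
        base_cols = [c for c in ("n_pct", "n_area", "p_mass", "p_area", "c_mass",
                                 "delta13c", "sla", "cn", "lai") if c in insitu.columns]
        base = insitu.loc[insitu.index.intersection(sync.index), base_cols].dropna()
        y_sync = sync.loc[base.index, "efp"].to_numpy(dtype=float)
        if len(base) > 5:
            candidates = expand_predictors(base)
            step = stepwise_aic(y_sync, candidates)
            linking_json["stepwise"] = {
                "selected": list(step.selected),
                "terms": {k: list(v) for k, v in step.terms.items()},
                "r2": step.r2, "adj_r2": step.adj_r2, "aic": step.aic, "n": step.n,
            }
        else:
            manifest.warnings.append("stepwise skipped: fewer than 6 synchronized sites")
        _json_write(linking_json, outdir / "linking.json")
        manifest.stage_counts["linking_sites"] = int(len(pts["site"].unique()))
    except PipelineError:
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.to_json(outdir / "manifest.json")
        raise
    except Exception as exc:
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.to_json(outdir / "manifest.json")
        raise PipelineError("unknown", str(exc)) from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(outdir / "manifest.json")
    return manifest
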