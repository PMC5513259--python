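"""Trait–capacity linking statistics.

Site-level ecosystem photosynthetic capacity (one scalar per site) is
related to community-weighted traits with:

* ordinary least squares with coefficient SEs, overall F-test, R²/adjusted
  R² (`ols`);
* distance correlation, for nonlinear association (shared implementation in
  :mod:`fluxefp.stats`);
* leave-one-out cross-validation summarized as modeling efficiency
  EF = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² (Nash–Sutcliffe form, ≤ 1, negative when worse
  than the mean) and RRMSE = 100·RMSE/mean(y) (`loocv_metrics`);
* ANCOVA F-tests for slope (interaction) and intercept (group) differences
  between synchronization scenarios (`ancova`);
* a year-resampling permutation test of whether using the trait-sampling
  year's capacity beats a random year (`year_resampling_test`);
* data-driven trait selection: candidate terms v, v², √v, log v and all
  pairwise ratios of base predictors (`expand_predictors`) searched by
  bidirectional stepwise regression under AIC = n·ln(RSS/n) + 2k
  (`stepwise_aic`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols as smf_ols

from .stats import distance_correlation, r_squared

__all__ = [
    "RegressionResult",
    "ols",
    "loocv_metrics",
    "ancova",
    "AncovaResult",
    "year_resampling_test",
    "expand_predictors",
    "stepwise_aic",
    "run_scenarios",
    "SCENARIOS",
]

#: the three synchronization scenarios: (capacity policy, trait source).
SCENARIOS = (
    ("multiyear_mean", "database"),
    ("multiyear_mean", "in_situ"),
    ("sampling_year", "in_situ"),
)


@dataclass
class RegressionResult:
    """One fitted linear model with diagnostics."""

    terms: dict  # name -> (coefficient, standard error); includes "intercept"
    r2: float
    adj_r2: float
    p_value: float  # overall F
    df_model: int
    df_resid: int
    n: int
    aic: float = np.nan  # n·ln(RSS/n) + 2k convention
    dcor: float = np.nan
    ef: float = np.nan
    rrmse: float = np.nan
    selected: tuple = field(default_factory=tuple)


def _design(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


def _check_rank(X: pd.DataFrame) -> None:
    """Raise naming the collinear term(s) if the design is rank-deficient."""
    mat = _design(X)
    if np.linalg.matrix_rank(mat) == mat.shape[1]:
        return
    culprits = []
    base = np.ones((len(X), 1))
    for name in X.columns:
        cand = np.column_stack([base, X[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > base.shape[1]:
            base = cand
        else:
            culprits.append(name)
    raise ValueError(f"rank-deficient design; collinear term(s): {culprits}")


def _aic_ls(y: np.ndarray, mat: np.ndarray) -> float:
    """AIC (constant terms dropped): n·ln(RSS/n) + 2k, k incl. intercept."""
    n = y.size
    coef, _, _, _ = np.linalg.lstsq(mat, y, rcond=None)
    rss = float(np.sum((y - mat @ coef) ** 2))
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * mat.shape[1]


def ols(y, X: pd.DataFrame) -> RegressionResult:
    """OLS of ``y`` on the term columns of ``X`` (intercept added).

    Raises
    ------
    ValueError
        If n ≤ number of terms + 1, or the design is rank-deficient (the
        error names the collinear terms).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X must have equal length")
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} terms")
    _check_rank(X)
    model = sm.OLS(y, sm.add_constant(X.astype(float), has_constant="add")).fit()
    names = ["intercept"] + list(X.columns)
    terms = {
        name: (float(model.params.iloc[i]), float(model.bse.iloc[i]))
        for i, name in enumerate(names)
    }
    constant_y = np.ptp(y) == 0.0  # R² of a constant response is 0 by contract
    return RegressionResult(
        terms=terms,
        r2=0.0 if constant_y else float(model.rsquared),
        adj_r2=0.0 if constant_y else float(model.rsquared_adj),
        p_value=float(model.f_pvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        n=len(y),
        aic=_aic_ls(y, _design(X)),
    )


def loocv_metrics(y, X: pd.DataFrame) -> tuple[float, float]:
    """Leave-one-out EF and RRMSE of the linear model ``y ~ X``.

    Refits with each point held out and scores the collected predictions:
    EF = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² (may be negative), RRMSE = 100·RMSE/mean(y).

    Raises
    ------
    ValueError
        If n < 3 or mean(y) is 0 (RRMSE undefined).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("LOOCV needs at least 3 points")
    if y.mean() == 0.0:
        raise ValueError("RRMSE undefined: mean of observations is 0")
    mat = _design(X)
    pred = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        coef, _, _, _ = np.linalg.lstsq(mat[keep], y[keep], rcond=None)
        pred[i] = mat[i] @ coef
    ef = r_squared(y, pred)
    rrmse = 100.0 * np.sqrt(np.mean((y - pred) ** 2)) / abs(y.mean())
    return float(ef), float(rrmse)


@dataclass(frozen=True)
class AncovaResult:
    """Slope-homogeneity and intercept-difference tests across groups."""

    interaction_f: float
    interaction_p: float  # slopes differ?
    group_f: float
    group_p: float  # intercepts differ (common slope)?
    n_groups: int
    n: int


def ancova(y, x, groups) -> AncovaResult:
    """ANCOVA of ``y ~ x`` across groups.

    The interaction F-test (``y ~ x*group`` vs ``y ~ x + group``) tests
    slope differences; the group F-test (``y ~ x + group`` vs ``y ~ x``)
    tests intercept differences under a common slope.

    Raises
    ------
    ValueError
        With fewer than 2 groups or any group smaller than 3.
    """
    df = pd.DataFrame({"y": np.asarray(y, float), "x": np.asarray(x, float),
                       "g": np.asarray(groups).astype(str)})
    counts = df["g"].value_counts()
    if len(counts) < 2:
        raise ValueError("ANCOVA needs at least 2 groups")
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"ANCOVA groups too small (n<3): {small}")
    m_x = smf_ols("y ~ x", df).fit()
    m_add = smf_ols("y ~ x + C(g)", df).fit()
    m_full = smf_ols("y ~ x * C(g)", df).fit()
    inter = sm.stats.anova_lm(m_add, m_full)
    grp = sm.stats.anova_lm(m_x, m_add)
    return AncovaResult(
        interaction_f=float(inter["F"].iloc[1]),
        interaction_p=float(inter["Pr(>F)"].iloc[1]),
        group_f=float(grp["F"].iloc[1]),
        group_p=float(grp["Pr(>F)"].iloc[1]),
        n_groups=int(len(counts)),
        n=len(df),
    )


def year_resampling_test(
    annual: pd.DataFrame,
    trait: pd.Series,
    sampling_year: dict,
    B: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation test: does the trait-sampling year's capacity beat a
    random year?

    ``annual`` holds columns (site, year, value); ``trait`` maps site to the
    community trait (e.g. N%); ``sampling_year`` maps site to its trait
    sampling year.  The observed R² (capacity-in-sampling-year ~ trait) is
    compared against B draws where each site contributes a uniformly random
    available year.  Empirical p = (1 + #{null R² ≥ observed}) / (B + 1).

    Raises
    ------
    ValueError
        If B < 1 or fewer than 3 sites are usable.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    by_site = {
        site: grp.dropna(subset=["value"]).set_index("year")["value"]
        for site, grp in annual.groupby("site")
    }
    sites = [s for s in by_site if s in trait.index and len(by_site[s]) >= 1
             and sampling_year.get(s) in by_site[s].index]
    if len(sites) < 3:
        raise ValueError("year_resampling_test needs >= 3 usable sites")
    x = trait.loc[sites].to_numpy(dtype=float)
    y_obs = np.array([by_site[s].loc[sampling_year[s]] for s in sites])
    obs_r2 = ols(y_obs, pd.DataFrame({"x": x})).r2

    null = np.empty(B)
    values = [by_site[s].to_numpy(dtype=float) for s in sites]
    for b in range(B):
        y_b = np.array([v[rng.integers(0, v.size)] for v in values])
        if np.ptp(y_b) == 0.0:
            null[b] = obs_r2  # degenerate constant draw: counts as >= observed
        else:
            null[b] = ols(y_b, pd.DataFrame({"x": x})).r2
    p = (1.0 + float(np.sum(null >= obs_r2))) / (B + 1.0)
    return {"observed_r2": float(obs_r2), "null_r2": null, "p_value": float(p), "n_sites": len(sites)}


def expand_predictors(
    base: pd.DataFrame,
    aliases: dict | None = None,
) -> pd.DataFrame:
    """Candidate term set for trait selection.

    For each base variable v: v, v², √v, log v (power terms dropped, with a
    warning-free skip, for variables violating positivity: log needs all
    values > 0, √ needs all ≥ 0); plus every ordered ratio vᵢ/vⱼ of base
    variables (skipped when the denominator has zeros).  ``aliases`` maps a
    ratio name to a base column that already measures the same quantity up
    to scale (stoichiometric identities: C/N is the carbon-to-nitrogen
    ratio, per-area contents are mass-based contents over SLA), so exact
    duplicates are not generated twice.  Ratios are formed from base
    variables only, keeping the set finite.
    """
    if aliases is None:
        aliases = {
            "c_mass/n_mass": "cn",
            "c_mass/n_pct": "cn",
            "p_mass/sla": "p_area",
            "n_mass/sla": "n_area",
            "n_pct/sla": "n_area",
        }
    out = {}
    cols = list(base.columns)
    for name in cols:
        v = base[name].to_numpy(dtype=float)
        out[name] = v
        out[f"{name}^2"] = v * v
        if np.all(v >= 0):
            out[f"sqrt({name})"] = np.sqrt(v)
        if np.all(v > 0):
            out[f"log({name})"] = np.log(v)
    for num in cols:
        for den in cols:
            if num == den:
                continue
            name = f"{num}/{den}"
            if aliases.get(name) in cols:
                continue
            d = base[den].to_numpy(dtype=float)
            if np.any(d == 0):
                continue
            out[name] = base[num].to_numpy(dtype=float) / d
    return pd.DataFrame(out, index=base.index)


def stepwise_aic(
    y,
    candidates: pd.DataFrame,
    direction: str = "both",
    max_terms: int | None = None,
    n_restarts: int = 5,
) -> RegressionResult:
    """Stepwise variable selection under AIC = n·ln(RSS/n) + 2k.

    Starts from the intercept-only model; at each step the single addition,
    removal or one-for-one replacement (``direction="both"``) that most
    lowers AIC is taken; stops when no move lowers AIC.  The replacement
    move lets the search leave a near-collinear proxy (e.g. a power
    transform of the true term) even when the model-size cap is reached,
    while AIC still decreases strictly at every step.  Candidates whose
    addition leaves the design rank-deficient are skipped (a duplicated
    column can never join a model already containing its twin).  Ties are
    broken by candidate-column order.  ``max_terms`` caps model size
    (default ``n // 5``, at least 1).

    With many near-collinear candidates the greedy path can stall on a
    proxy of the true term, so the search restarts from each of the
    ``n_restarts - 1`` best single-term models in addition to the
    intercept-only start; the final model with the lowest AIC wins
    (deterministic; ties go to the earlier start).

    Raises
    ------
    ValueError
        If n ≤ 5.
    """
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= 5:
        raise ValueError("stepwise selection needs n > 5")
    if max_terms is None:
        max_terms = max(n // 5, 1)
    names = list(candidates.columns)
    cols = {name: candidates[name].to_numpy(dtype=float) for name in names}

    def matrix(sel: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [cols[s] for s in sel])

    def greedy(start: list[str]) -> tuple[list[str], float]:
        selected = list(start)
        current_aic = _aic_ls(y, matrix(selected))
        while True:
            best_move, best_aic = None, current_aic
            if direction in ("both", "forward") and len(selected) < max_terms:
                for name in names:
                    if name in selected:
                        continue
                    mat = matrix(selected + [name])
                    if np.linalg.matrix_rank(mat) < mat.shape[1]:
                        continue
                    a = _aic_ls(y, mat)
                    if a < best_aic - 1e-10:
                        best_move, best_aic = ("add", name, None), a
            if direction in ("both", "backward"):
                for name in selected:
                    a = _aic_ls(y, matrix([s for s in selected if s != name]))
                    if a < best_aic - 1e-10:
                        best_move, best_aic = ("drop", name, None), a
            if direction == "both":
                for incoming in names:
                    if incoming in selected:
                        continue
                    for outgoing in selected:
                        trial = [s for s in selected if s != outgoing] + [incoming]
                        mat = matrix(trial)
                        if np.linalg.matrix_rank(mat) < mat.shape[1]:
                            continue
                        a = _aic_ls(y, mat)
                        if a < best_aic - 1e-10:
                            best_move, best_aic = ("swap", incoming, outgoing), a
            if best_move is None:
                return selected, current_aic
            op, name, other = best_move
            if op == "add":
                selected.append(name)
            elif op == "drop":
                selected.remove(name)
            else:
                selected.remove(other)
                selected.append(name)
            current_aic = best_aic

    if direction == "backward":
        starts = [names[:max_terms]]
    else:
        starts = [[]]
        if direction == "both" and n_restarts > 1:
            single_aic = sorted(
                (( _aic_ls(y, matrix([name])), i, name)
                 for i, name in enumerate(names)),
                key=lambda t: (t[0], t[1]),
            )
            starts += [[name] for _, _, name in single_aic[: n_restarts - 1]]
    selected, current_aic = greedy(starts[0])
    for start in starts[1:]:
        sel, aic = greedy(start)
        if aic < current_aic - 1e-10:
            selected, current_aic = sel, aic

    if selected:
        result = ols(y, candidates[selected])
    else:
        intercept = float(y.mean())
        se = float(y.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        result = RegressionResult(
            terms={"intercept": (intercept, se)},
            r2=0.0, adj_r2=0.0, p_value=np.nan,
            df_model=0, df_resid=n - 1, n=n,
            aic=current_aic,
        )
    result.selected = tuple(selected)
    result.aic = current_aic
    return result


def scenario_points(
    annual: pd.DataFrame,
    community: pd.DataFrame,
    sampling_year: dict,
    trait: str = "n_pct",
) -> pd.DataFrame:
    """Per-site (capacity, trait) pairs for each synchronization scenario.

    Returns a long table (scenario, site, efp, trait) where ``scenario`` is
    ``"<efp_policy>|<trait_source>"`` — the input to both the scenario table
    and the cross-scenario ANCOVA.
    """
    rows = []
    for policy, source in SCENARIOS:
        tr = community.loc[community["source"] == source].set_index("site")[trait]
        for site, grp in annual.groupby("site"):
            if site not in tr.index:
                continue
            vals = grp.dropna(subset=["value"]).set_index("year")["value"]
            if vals.empty:
                continue
            if policy == "multiyear_mean":
                y_val = float(vals.mean())
            elif sampling_year.get(site) in vals.index:
                y_val = float(vals.loc[sampling_year[site]])
            else:
                continue
            rows.append(
                {"scenario": f"{policy}|{source}", "site": site,
                 "efp": y_val, "trait": float(tr.loc[site])}
            )
    return pd.DataFrame(rows)


def run_scenarios(
    annual: pd.DataFrame,
    community: pd.DataFrame,
    sampling_year: dict,
    trait: str = "n_pct",
) -> pd.DataFrame:
    """Table of linking statistics for the three synchronization scenarios.

    ``annual``: (site, year, value) for the chosen capacity estimator;
    ``community``: per-site trait table with a ``source`` column
    (in_situ/database); ``sampling_year`` maps site to trait-sampling year.
    Scenarios: multiyear-mean capacity vs database traits (no
    synchronization), multiyear-mean vs in-situ traits (space), and
    sampling-year capacity vs in-situ traits (space and time).
    """
    points = scenario_points(annual, community, sampling_year, trait)
    rows = []
    for policy, source in SCENARIOS:
        label = f"{policy}|{source}"
        sub = points.loc[points["scenario"] == label]
        if len(sub) < 4:
            raise ValueError(f"scenario ({policy}, {source}): too few sites ({len(sub)})")
        y_arr = sub["efp"].to_numpy(dtype=float)
        x_arr = sub["trait"].to_numpy(dtype=float)
        X = pd.DataFrame({trait: x_arr})
        res = ols(y_arr.astype(float), X)
        ef, rrmse = loocv_metrics(y_arr.astype(float), X)
        rows.append(
            {
                "efp_policy": policy,
                "trait_source": source,
                "n_sites": len(sub),
                "dcor": distance_correlation(x_arr.astype(float), y_arr.astype(float)),
                "r2": res.r2,
                "adj_r2": res.adj_r2,
                "intercept": res.terms["intercept"][0],
                "intercept_se": res.terms["intercept"][1],
                "slope": res.terms[trait][0],
                "slope_se": res.terms[trait][1],
                "p": res.p_value,
                "ef": ef,
                "rrmse": rrmse,
            }
        )
    return pd.DataFrame(rows)
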