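"""Proportion of floating objects occupied by tuna (f-hat) and its
species-level refinement.

Echosounder buoys report a daily presence/absence of tuna (detection
threshold 1 t). After discarding each buoy's initial colonization period,
the daily fraction of occupied buoys is computed per stratum (subject to a
minimum daily buoy count), averaged into a per-stratum occupancy f-hat,
and split by species through the occurrence rate eta_i — the share of
sampled sets catching at least 1 t of species i — giving

    f_i = f_hat * eta_i.

Missing occurrence rates are imputed from a binomial regression on year,
quarter and region. A unit-root check on the daily occupancy series is
provided as a within-stratum homogeneity diagnostic.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from statsmodels.tsa.stattools import adfuller

from .strata import STRATUM_COLS, RegionSet

log = logging.getLogger(__name__)

DEFAULT_MIN_BUOYS = 30
DEFAULT_MIN_SETS = 20
DEFAULT_DETECTION_THRESHOLD = 1.0  # tonnes
ETA_PREDICTORS = ("year", "quarter", "region_id")


def trim_colonization(buoydays: pd.DataFrame) -> pd.DataFrame:
    """Drop each buoy's leading run of absences (the colonization period).

    Buoys that never show a presence are removed entirely. Nothing after a
    buoy's first presence is ever removed.
    """
    df = buoydays.sort_values(["buoy_id", "date"], kind="mergesort")
    colonized = df.groupby("buoy_id")["present"].cummax()
    return df[colonized.astype(bool)].reset_index(drop=True)


def daily_fraction(buoydays: pd.DataFrame, regions: RegionSet,
                   min_buoys: int = DEFAULT_MIN_BUOYS) -> pd.DataFrame:
    """Daily per-stratum fraction of occupied buoys.

    Days with fewer than ``min_buoys`` reporting buoys in the stratum are
    dropped. Expects colonization-trimmed input.
    """
    assigned = regions.assign_frame(buoydays)
    daily = (assigned.groupby(STRATUM_COLS + ["date"])
             .agg(n_buoys=("buoy_id", "nunique"), n_occupied=("present", "sum"))
             .reset_index())
    daily["n_occupied"] = daily["n_occupied"].astype(int)
    under = daily["n_buoys"] < min_buoys
    if under.any():
        log.info("daily_fraction: dropped %d stratum-days under the %d-buoy "
                 "threshold", int(under.sum()), min_buoys)
    daily = daily[~under].reset_index(drop=True)
    daily["fraction"] = daily["n_occupied"] / daily["n_buoys"]
    return daily


def stratum_occupancy(daily: pd.DataFrame) -> pd.DataFrame:
    """f-hat per stratum: unweighted mean of the retained daily fractions."""
    out = (daily.groupby(STRATUM_COLS)
           .agg(f_hat=("fraction", "mean"), n_days=("date", "nunique"))
           .reset_index())
    return out


def occurrence_rate(sets: pd.DataFrame, samples: pd.DataFrame,
                    regions: RegionSet,
                    threshold: float = DEFAULT_DETECTION_THRESHOLD,
                    min_sets: int = DEFAULT_MIN_SETS,
                    species: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-stratum, per-species occurrence rate eta from sampled sets.

    eta = #{sampled sets with >= ``threshold`` tonnes of the species} /
    #{sampled sets}; the species catch of a set is corrected_catch x its
    sampled proportion. Strata under ``min_sets`` sampled sets are emitted
    missing. All strata present in ``sets`` are emitted.
    """
    assigned = regions.assign_frame(sets)
    strata = assigned[STRATUM_COLS].drop_duplicates().reset_index(drop=True)
    sampled = assigned[assigned["sampled"].astype(bool)]
    if species is None:
        species = sorted(samples["species"].unique())
    species = list(species)

    wide = (samples.pivot_table(index="set_id", columns="species",
                                values="proportion", aggfunc="sum")
            .reindex(columns=species).fillna(0.0))
    per_set = sampled[STRATUM_COLS + ["set_id", "corrected_catch"]].join(wide, on="set_id")
    per_set[species] = per_set[species].fillna(0.0)
    for sp in species:
        per_set[sp] = (per_set[sp] * per_set["corrected_catch"] >= threshold)

    agg = per_set.groupby(STRATUM_COLS)
    occ = agg[species].sum()
    n = agg["set_id"].nunique().rename("n_sampled_sets")
    table = occ.join(n).reset_index()
    table = strata.merge(table, on=STRATUM_COLS, how="left")
    table["n_sampled_sets"] = table["n_sampled_sets"].fillna(0).astype(int)
    table[species] = table[species].fillna(0)

    long = table.melt(id_vars=STRATUM_COLS + ["n_sampled_sets"],
                      value_vars=species, var_name="species",
                      value_name="n_occurrences")
    long["n_occurrences"] = long["n_occurrences"].astype(int)
    long["eta_hat"] = np.where(long["n_sampled_sets"] >= min_sets,
                               long["n_occurrences"] / long["n_sampled_sets"].replace(0, np.nan),
                               np.nan)
    long["imputed"] = False
    return long.sort_values(STRATUM_COLS + ["species"]).reset_index(drop=True)


def impute_eta_binomial(table: pd.DataFrame,
                        predictors: Sequence[str] = ETA_PREDICTORS) -> pd.DataFrame:
    """Fill missing occurrence rates from a logit-link binomial regression.

    Per species, occurrence counts out of sampled-set counts are regressed
    on additive year + quarter + region factors; missing cells receive the
    predicted probability. On separation, non-convergence, or factor levels
    unseen among observed cells, the species' pooled observed rate is used.
    """
    out = table.copy()
    rhs = " + ".join(f"C({p})" for p in predictors)
    for sp, grp in out.groupby("species"):
        obs = grp[grp["eta_hat"].notna() & (grp["n_sampled_sets"] > 0)]
        mis = grp[grp["eta_hat"].isna()]
        if len(mis) == 0:
            continue
        if len(obs) == 0:
            raise ValueError(f"no observed occurrence data for species {sp!r}")
        pooled = obs["n_occurrences"].sum() / obs["n_sampled_sets"].sum()
        pred = np.full(len(mis), pooled)
        seen = {p: set(obs[p].unique()) for p in predictors}
        in_support = np.ones(len(mis), dtype=bool)
        for p in predictors:
            in_support &= mis[p].isin(seen[p]).to_numpy()
        if in_support.any():
            try:
                exog = patsy.dmatrix(rhs, obs, return_type="dataframe")
                endog = np.column_stack([
                    obs["n_occurrences"],
                    obs["n_sampled_sets"] - obs["n_occurrences"],
                ])
                res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
                exog_mis = patsy.build_design_matrices(
                    [exog.design_info], mis[in_support],
                    return_type="dataframe")[0]
                p_hat = np.asarray(res.predict(exog_mis))
                if not np.all(np.isfinite(p_hat)):
                    raise ValueError("non-finite predictions")
                pred[in_support] = p_hat
            except Exception as err:  # separation / convergence / design failures
                log.warning("impute_eta_binomial[%s]: %s; falling back to the "
                            "pooled observed rate %.4f", sp, err, pooled)
        if (~in_support).any():
            log.warning("impute_eta_binomial[%s]: %d cell(s) with unseen factor "
                        "levels; using the pooled observed rate", sp,
                        int((~in_support).sum()))
        out.loc[mis.index, "eta_hat"] = np.clip(pred, 0.0, 1.0)
        out.loc[mis.index, "imputed"] = True
    return out


def species_occupancy(f_hat, eta_hat):
    """Species-level occupancy f_i = f_hat * eta_i (scalars or arrays)."""
    f = np.asarray(f_hat, dtype=float)
    e = np.asarray(eta_hat, dtype=float)
    if np.any((f < 0) | (f > 1)) or np.any((e < 0) | (e > 1)):
        raise ValueError("f_hat and eta_hat must lie in [0, 1]")
    out = f * e
    return float(out) if out.ndim == 0 else out


def species_occupancy_table(occupancy: pd.DataFrame,
                            eta: pd.DataFrame) -> pd.DataFrame:
    """Join per-stratum f-hat with per-stratum/species eta into f_i."""
    merged = occupancy.merge(eta, on=STRATUM_COLS, how="inner")
    merged["f_i"] = species_occupancy(merged["f_hat"].to_numpy(),
                                      merged["eta_hat"].to_numpy())
    return merged


def stationarity_check(daily: pd.DataFrame, alpha: float = 0.05,
                       min_obs: int = 30) -> pd.DataFrame:
    """Augmented Dickey–Fuller unit-root check of each stratum's daily series.

    The occupancy fraction should be stationary within a stratum if
    conditions there are homogeneous; a unit root signals drift. Constant
    series are reported stationary; series shorter than ``min_obs`` as
    'insufficient data'.
    """
    rows = []
    for key, grp in daily.groupby(STRATUM_COLS):
        series = grp.sort_values("date")["fraction"].to_numpy(dtype=float)
        rec = dict(zip(STRATUM_COLS, key))
        rec["n_obs"] = len(series)
        if len(series) < min_obs:
            rec.update(adf_stat=np.nan, pvalue=np.nan, verdict="insufficient data")
        elif np.ptp(series) == 0.0:
            rec.update(adf_stat=np.nan, pvalue=0.0, verdict="stationary")
        else:
            stat, pvalue, *_ = adfuller(series, regression="c", autolag="AIC")
            rec.update(adf_stat=stat, pvalue=pvalue,
                       verdict="stationary" if pvalue < alpha else "non-stationary")
        rows.append(rec)
    return pd.DataFrame(rows)
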