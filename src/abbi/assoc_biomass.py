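"""Average per-species biomass associated with a floating object (m-hat).

Logbook catch-per-set values are first reconciled against trip landing
totals (Level-1 correction), species/size compositions from port sampling
are averaged per stratum (Level 2) with a minimum-sample threshold and
linear-model imputation of missing strata, and the two are multiplied into
the per-stratum mean associated biomass per species.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .strata import STRATUM_COLS, RegionSet

log = logging.getLogger(__name__)

DEFAULT_MIN_SETS = 20
EMM_PREDICTORS = ("year", "quarter", "region_id")


def level1_correct(sets: pd.DataFrame, landings: pd.DataFrame) -> pd.DataFrame:
    """Scale declared catch-per-set so each trip's total matches its landing.

    Within a trip: corrected = declared x landed_total / sum(declared).
    Trips without a landing record, and trips with zero declared total but
    positive landings, are left uncorrected and flagged.
    """
    out = sets.copy()
    declared_tot = out.groupby("trip_id")["declared_catch"].transform("sum")
    landed = out["trip_id"].map(landings.set_index("trip_id")["landed_total"])

    no_landing = landed.isna()
    zero_declared = (declared_tot == 0) & (landed > 0)
    ok = ~no_landing & ~zero_declared & (declared_tot > 0)
    zero_both = ~no_landing & (declared_tot == 0) & (landed == 0)

    ratio = pd.Series(1.0, index=out.index)
    ratio[ok] = landed[ok] / declared_tot[ok]
    out["corrected_catch"] = out["declared_catch"] * ratio
    out["level1_applied"] = (ok | zero_both).to_numpy()

    if no_landing.any():
        trips = sorted(out.loc[no_landing, "trip_id"].unique())
        log.warning("level1_correct: no landing record for %d trip(s) %s; "
                    "left uncorrected", len(trips), trips[:5])
    if zero_declared.any():
        trips = sorted(out.loc[zero_declared, "trip_id"].unique())
        log.warning("level1_correct: %d trip(s) with zero declared total but "
                    "positive landing %s; left uncorrected", len(trips), trips[:5])
    return out


def stratum_composition(sets: pd.DataFrame, samples: pd.DataFrame,
                        regions: RegionSet,
                        min_sets: int = DEFAULT_MIN_SETS,
                        species: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-stratum mean species composition from the sampled sets.

    ``sets`` is the full set stream (sampled and not); ``samples`` holds
    per-set proportions (set_id, species, proportion) for sampled sets, a
    missing species row meaning proportion zero. Strata with fewer than
    ``min_sets`` sampled sets are emitted with a missing mean, to be filled
    by :func:`impute_composition_emm`. All strata present in ``sets`` are
    emitted, so downstream joins never silently drop a stratum.
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
    per_set = sampled[STRATUM_COLS + ["set_id"]].join(wide, on="set_id")
    per_set[species] = per_set[species].fillna(0.0)

    agg = per_set.groupby(STRATUM_COLS)
    means = agg[species].mean()
    n = agg["set_id"].nunique().rename("n_sampled_sets")
    table = means.join(n).reset_index()
    table = strata.merge(table, on=STRATUM_COLS, how="left")
    table["n_sampled_sets"] = table["n_sampled_sets"].fillna(0).astype(int)

    long = table.melt(id_vars=STRATUM_COLS + ["n_sampled_sets"],
                      value_vars=species, var_name="species",
                      value_name="mean_proportion")
    below = long["n_sampled_sets"] < min_sets
    long.loc[below, "mean_proportion"] = np.nan
    long["imputed"] = False
    return long.sort_values(STRATUM_COLS + ["species"]).reset_index(drop=True)


def impute_composition_emm(table: pd.DataFrame,
                           predictors: Sequence[str] = EMM_PREDICTORS) -> pd.DataFrame:
    """Fill missing stratum compositions with estimated marginal means.

    Per species, an additive fixed-effects linear model of the observed
    mean proportions on year + quarter + region is fitted; each missing
    cell receives the model prediction for its factor combination, clipped
    to [0, 1]. Cells whose factor level never appears among observed cells
    fall back to the species' observed mean.
    """
    out = table.copy()
    formula = "mean_proportion ~ " + " + ".join(f"C({p})" for p in predictors)
    for sp, grp in out.groupby("species"):
        obs = grp[grp["mean_proportion"].notna()]
        mis = grp[grp["mean_proportion"].isna()]
        if len(mis) == 0:
            continue
        if len(obs) == 0:
            raise ValueError(f"no observed composition for species {sp!r}: "
                             "cannot impute")
        seen = {p: set(obs[p].unique()) for p in predictors}
        in_support = np.ones(len(mis), dtype=bool)
        for p in predictors:
            in_support &= mis[p].isin(seen[p]).to_numpy()
        pred = np.full(len(mis), obs["mean_proportion"].mean())
        if in_support.any():
            model = smf.ols(formula, data=obs).fit()
            pred[in_support] = model.predict(mis[in_support])
        if (~in_support).any():
            log.warning("impute_composition_emm[%s]: %d cell(s) with factor "
                        "levels unseen among observed strata; using the "
                        "species' pooled mean", sp, int((~in_support).sum()))
        out.loc[mis.index, "mean_proportion"] = np.clip(pred, 0.0, 1.0)
        out.loc[mis.index, "imputed"] = True
    return out


def estimate_m(sets: pd.DataFrame, composition: pd.DataFrame,
               regions: RegionSet,
               min_sets: int = DEFAULT_MIN_SETS) -> pd.DataFrame:
    """Mean associated biomass per species and stratum.

    m-hat = mean Level-1-corrected catch over *all* object sets in the
    stratum x mean species proportion. Strata with fewer than ``min_sets``
    total sets are excluded from the index.
    """
    if composition["mean_proportion"].isna().any():
        raise ValueError("composition table still has missing entries; "
                         "run impute_composition_emm first")
    assigned = regions.assign_frame(sets)
    per_stratum = (assigned.groupby(STRATUM_COLS)
                   .agg(mean_catch=("corrected_catch", "mean"),
                        n_sets=("set_id", "nunique"))
                   .reset_index())
    kept = per_stratum[per_stratum["n_sets"] >= min_sets]
    dropped = len(per_stratum) - len(kept)
    if dropped:
        log.info("estimate_m: %d strata excluded (< %d sets)", dropped, min_sets)
    merged = kept.merge(composition, on=STRATUM_COLS, how="left", indicator=True)
    orphans = merged["_merge"] == "left_only"
    if orphans.any():
        bad = merged.loc[orphans, STRATUM_COLS].drop_duplicates()
        raise ValueError("strata present in sets but absent from the "
                         f"composition table:\n{bad.to_string(index=False)}")
    merged["m_hat"] = merged["mean_catch"] * merged["mean_proportion"]
    cols = STRATUM_COLS + ["species", "m_hat", "n_sets", "imputed"]
    return merged[cols].sort_values(STRATUM_COLS + ["species"]).reset_index(drop=True)
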