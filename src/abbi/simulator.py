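"""Synthetic associative dynamics with known ground truth.

Schools of fish alternate between an associated state (resident at one
floating object, mean sojourn CRT) and an unassociated state (mean sojourn
CAT = 1/(phi x number of objects)), the renewal structure from which the
abundance identity X_a/N = CRT/(CRT+CAT) emerges. Each region of the study
area is simulated as a closed system: its schools associate only with its
objects, matching the homogeneity assumption behind the stratified
estimator. Observation layers — buoy presence/absence with a detection
threshold and a colonization mask, purse-seine sets with noisy declared
catches, trip landings and port sampling — reproduce the input schemas of
the estimation modules, so the full pipeline can be validated by parameter
recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .behaviour import BET_SMALL, SKJ, YFT_SMALL, default_registry
from .strata import RegionSet, default_region_set

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesSim:
    """Per-species generator settings.

    School biomass is log-normal; the defaults give a mean school size of
    about 23 t, on the order of purse-seine catches at floating objects.
    """

    n_schools: int
    crt_days: float
    biomass_meanlog: float = 3.0  # log-tonnes
    biomass_sdlog: float = 0.5

    def __post_init__(self):
        if self.n_schools < 0 or self.crt_days <= 0 or self.biomass_sdlog < 0:
            raise ValueError("invalid species configuration")


def _default_species() -> Dict[str, SpeciesSim]:
    reg = default_registry()
    # Relative school numbers mirror the catch dominance of skipjack over
    # small yellowfin and bigeye at floating objects.
    return {
        SKJ: SpeciesSim(600, reg[SKJ].crt_mean),
        YFT_SMALL: SpeciesSim(200, reg[YFT_SMALL].crt_mean),
        BET_SMALL: SpeciesSim(80, reg[BET_SMALL].crt_mean),
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``phi`` sets the per-object association rate, so the mean absence time
    in a region with ``n`` objects is 1/(phi*n); ``cat_days``, when given,
    fixes the mean absence time directly and overrides ``phi``.
    """

    seed: int = 0
    n_fobs: int = 1500
    horizon_days: int = 90
    start_date: str = "2013-01-01"
    regions: Optional[RegionSet] = None
    species: Optional[Dict[str, SpeciesSim]] = None
    phi: float = 6e-5
    cat_days: Optional[float] = None
    detection_threshold: float = 1.0  # tonnes
    colonization_lag_days: int = 7
    set_rate: float = 0.02           # sets per occupied object-day
    sampled_fraction: float = 0.5
    declaration_sigma: float = 0.2   # log-sd of declared-catch noise
    sets_per_trip: int = 10
    extractive: bool = False
    sojourn_dist: str = "exponential"  # or "gamma"
    gamma_shape: float = 2.0
    drift_step_deg: float = 0.1
    #: 'empty' starts every school unassociated, so each buoy's leading
    #: absence run genuinely is the colonization of a freshly deployed
    #: array (what the trimming step assumes); 'stationary' draws initial
    #: states from the equilibrium of the two-state process.
    start_state: str = "empty"

    def __post_init__(self):
        if self.regions is None:
            self.regions = default_region_set()
        if self.species is None:
            self.species = _default_species()
        if self.n_fobs < len(self.regions):
            raise ValueError("need at least one floating object per region")
        if self.horizon_days <= 0:
            raise ValueError("horizon must be positive")
        if not (0.0 <= self.sampled_fraction <= 1.0):
            raise ValueError("sampled_fraction must lie in [0, 1]")
        if self.phi <= 0 or (self.cat_days is not None and self.cat_days <= 0):
            raise ValueError("phi (and cat_days if given) must be positive")
        if self.set_rate < 0 or self.detection_threshold < 0:
            raise ValueError("set_rate and detection_threshold must be >= 0")
        if self.sojourn_dist not in ("exponential", "gamma"):
            raise ValueError(f"unknown sojourn distribution {self.sojourn_dist!r}")
        if self.start_state not in ("empty", "stationary"):
            raise ValueError(f"unknown start_state {self.start_state!r}")


@dataclass
class SimResult:
    buoy_days: pd.DataFrame
    sets: pd.DataFrame
    landings: pd.DataFrame
    samples: pd.DataFrame
    gridded_counts: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def _split_even(total: int, k: int) -> List[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] (billiard reflection)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def _draw_sojourn(rng, mean: float, kind: str, shape: float) -> float:
    if kind == "gamma":
        return rng.gamma(shape, mean / shape)
    return rng.exponential(mean)


def _simulate_school(rng, horizon, crt, cat, n_fobs_region, fob_offset,
                     kind, shape, start_state):
    """One school's association intervals [(fob, t0, t1)] plus completed sojourns."""
    if start_state == "stationary":
        associated = rng.random() < crt / (crt + cat)
    else:
        associated = False
    t = 0.0
    intervals, crts, cats = [], [], []
    while t < horizon:
        if associated:
            dur = _draw_sojourn(rng, crt, kind, shape)
            fob = fob_offset + int(rng.integers(n_fobs_region))
            intervals.append((fob, t, min(t + dur, horizon)))
            if t + dur <= horizon:
                crts.append(dur)
        else:
            dur = _draw_sojourn(rng, cat, kind, shape)
            if t + dur <= horizon:
                cats.append(dur)
        t += dur
        associated = not associated
    return intervals, crts, cats


def _intervals_to_days(intervals: np.ndarray, horizon: int):
    """Days d whose sampling instant d+0.5 falls in [t0, t1)."""
    fob, t0, t1 = intervals[:, 0].astype(int), intervals[:, 1], intervals[:, 2]
    d0 = np.ceil(t0 - 0.5).astype(int)
    d1 = np.ceil(t1 - 0.5).astype(int)  # exclusive
    d0 = np.clip(d0, 0, horizon)
    d1 = np.clip(d1, 0, horizon)
    counts = np.maximum(d1 - d0, 0)
    rows = np.repeat(np.arange(len(intervals)), counts)
    days = np.concatenate([np.arange(a, b) for a, b in zip(d0, d1) if b > a]) \
        if counts.sum() else np.empty(0, dtype=int)
    return np.repeat(fob, counts), days, rows


def simulate(config: SimConfig) -> SimResult:
    """Generate one synthetic dataset; identical seed gives identical tables."""
    regions = config.regions
    n_regions = len(regions)
    horizon = config.horizon_days
    start = pd.Timestamp(config.start_date)
    dates = pd.to_datetime(start + pd.to_timedelta(np.arange(horizon), unit="D"))

    ss = np.random.SeedSequence(config.seed)
    rng_fob, rng_school, rng_set, rng_sample, rng_decl = (
        np.random.default_rng(s) for s in ss.spawn(5))

    fobs_per_region = _split_even(config.n_fobs, n_regions)
    fob_region = np.repeat(np.arange(n_regions), fobs_per_region)
    fob_offsets = np.concatenate([[0], np.cumsum(fobs_per_region)[:-1]])

    # Object drift: a reflected random walk confined to the home cell.
    lat = np.empty((config.n_fobs, horizon))
    lon = np.empty((config.n_fobs, horizon))
    for ri, region in enumerate(regions):
        sel = fob_region == ri
        n = int(sel.sum())
        la0 = rng_fob.uniform(region.lat_min, region.lat_min + regions.cell_size, n)
        lo0 = rng_fob.uniform(region.lon_min, region.lon_min + regions.cell_size, n)
        steps = rng_fob.normal(0.0, config.drift_step_deg, size=(2, n, horizon - 1))
        la = np.concatenate([la0[:, None], la0[:, None] + steps[0].cumsum(axis=1)], axis=1)
        lo = np.concatenate([lo0[:, None], lo0[:, None] + steps[1].cumsum(axis=1)], axis=1)
        eps = 1e-9  # keep strictly below the upper cell edge
        lat[sel] = _reflect(la, region.lat_min, region.lat_min + regions.cell_size - eps)
        lon[sel] = _reflect(lo, region.lon_min, region.lon_min + regions.cell_size - eps)

    # Two-state residency dynamics, one closed pool per region.
    interval_store = []  # (species, school_gid, biomass, fob, t0, t1)
    truth_rows = []
    school_gid = 0
    for sp, spec in config.species.items():
        n_per_region = _split_even(spec.n_schools, n_regions)
        cat_mean = (config.cat_days if config.cat_days is not None
                    else 1.0 / (config.phi * np.array(fobs_per_region, dtype=float)))
        cat_by_region = (np.full(n_regions, cat_mean) if np.ndim(cat_mean) == 0
                         else cat_mean)
        biomass = rng_school.lognormal(spec.biomass_meanlog, spec.biomass_sdlog,
                                       spec.n_schools)
        all_crts, all_cats = [], []
        assoc_time = 0.0
        b_idx = 0
        for ri in range(n_regions):
            for _ in range(n_per_region[ri]):
                ivs, crts, cats = _simulate_school(
                    rng_school, horizon, spec.crt_days, float(cat_by_region[ri]),
                    fobs_per_region[ri], int(fob_offsets[ri]),
                    config.sojourn_dist, config.gamma_shape, config.start_state)
                all_crts.extend(crts)
                all_cats.extend(cats)
                b = biomass[b_idx]
                for fob, t0, t1 in ivs:
                    interval_store.append((sp, school_gid, b, fob, t0, t1))
                    assoc_time += b * (t1 - t0)
                b_idx += 1
                school_gid += 1
        total_b = float(biomass.sum())
        cat_cfg = (config.cat_days if config.cat_days is not None
                   else 1.0 / (config.phi * config.n_fobs / n_regions))
        truth_rows.append(dict(
            species=sp, n_schools=spec.n_schools, true_biomass=total_b,
            crt_config=spec.crt_days, cat_config=float(cat_cfg),
            realized_mean_crt=float(np.mean(all_crts)) if all_crts else np.nan,
            realized_mean_cat=float(np.mean(all_cats)) if all_cats else np.nan,
            n_completed_crt=len(all_crts), n_completed_cat=len(all_cats),
            realized_associated_fraction=assoc_time / (total_b * horizon)
            if total_b > 0 else np.nan,
        ))
    truth = pd.DataFrame(truth_rows)

    if interval_store:
        iv = pd.DataFrame(interval_store,
                          columns=["species", "school", "biomass", "fob", "t0", "t1"])
        fob_arr, day_arr, row_arr = _intervals_to_days(
            iv[["fob", "t0", "t1"]].to_numpy(dtype=float), horizon)
        assoc = pd.DataFrame({
            "fob": fob_arr, "day": day_arr,
            "species": iv["species"].to_numpy()[row_arr],
            "school": iv["school"].to_numpy()[row_arr],
            "biomass": iv["biomass"].to_numpy()[row_arr],
        })
    else:
        assoc = pd.DataFrame(columns=["fob", "day", "species", "school", "biomass"])

    removed_after: Dict[int, int] = {}
    set_events = _draw_sets(assoc, config, rng_set, removed_after)
    if config.extractive and removed_after:
        removal_day = assoc["school"].map(removed_after)
        caught = (assoc[assoc["school"].isin(removed_after)]
                  [["species", "school", "biomass"]].drop_duplicates())
        removed_biomass = caught.groupby("species")["biomass"].sum()
        truth["true_biomass_final"] = (
            truth["true_biomass"]
            - truth["species"].map(removed_biomass).fillna(0.0))
        assoc = assoc[removal_day.isna() | (assoc["day"] <= removal_day)]
    else:
        truth["true_biomass_final"] = truth["true_biomass"]

    fobday_total = (assoc.groupby(["fob", "day"])["biomass"].sum()
                    .rename("total_biomass"))

    # Buoy-day observation layer: every object carries a reporting buoy.
    n_rows = config.n_fobs * horizon
    fob_idx = np.repeat(np.arange(config.n_fobs), horizon)
    day_idx = np.tile(np.arange(horizon), config.n_fobs)
    totals = fobday_total.reindex(
        pd.MultiIndex.from_arrays([fob_idx, day_idx]), fill_value=0.0).to_numpy()
    present = (totals >= config.detection_threshold) & \
        (day_idx >= config.colonization_lag_days)
    buoy_days = pd.DataFrame({
        "buoy_id": np.char.add("B", np.char.zfill(fob_idx.astype(str), 5)),
        "date": dates[day_idx],
        "lat": lat[fob_idx, day_idx],
        "lon": lon[fob_idx, day_idx],
        "present": present,
        "days_since_deployment": day_idx,
    })

    sets, landings, samples = _observe_fishery(
        set_events, assoc, config, dates, lat, lon, rng_sample, rng_decl)

    gridded = _grid_counts(buoy_days)
    return SimResult(buoy_days, sets, landings, samples, gridded, truth, config)


def _draw_sets(assoc: pd.DataFrame, config: SimConfig, rng,
               removed_after: Dict[int, int]) -> pd.DataFrame:
    """Bernoulli set events on occupied object-days past the colonization lag."""
    if len(assoc) == 0:
        return pd.DataFrame(columns=["fob", "day"])
    totals = assoc.groupby(["fob", "day"])["biomass"].sum().reset_index()
    occ = totals[(totals["biomass"] >= config.detection_threshold)
                 & (totals["day"] >= config.colonization_lag_days)]
    hits = occ[rng.random(len(occ)) < config.set_rate]
    events = hits.sort_values(["day", "fob"]).reset_index(drop=True)
    if config.extractive and len(events):
        # Chronological harvesting: a school can be caught only once.
        kept = []
        sch = assoc.set_index(["fob", "day"]).sort_index()
        for _, ev in events.iterrows():
            key = (int(ev["fob"]), int(ev["day"]))
            try:
                here = sch.loc[[key]]
            except KeyError:
                continue
            alive = [s for s in here["school"]
                     if removed_after.get(s, np.inf) >= ev["day"]]
            if not alive:
                continue
            for s in alive:
                removed_after[s] = int(ev["day"])
            kept.append(ev)
        events = pd.DataFrame(kept).reset_index(drop=True) if kept else \
            pd.DataFrame(columns=["fob", "day"])
    return events[["fob", "day"]]


def _observe_fishery(events: pd.DataFrame, assoc: pd.DataFrame,
                     config: SimConfig, dates, lat, lon, rng_sample, rng_decl):
    set_cols = ["trip_id", "set_id", "date", "lat", "lon",
                "declared_catch", "true_catch", "sampled"]
    if len(events) == 0:
        log.warning("simulate: no purse-seine sets generated")
        return (pd.DataFrame(columns=set_cols),
                pd.DataFrame(columns=["trip_id", "landed_total"]),
                pd.DataFrame(columns=["set_id", "species", "proportion"]))
    events = events.reset_index(drop=True).copy()
    events["set_id"] = [f"S{i:06d}" for i in range(len(events))]
    events["trip_id"] = [f"T{i // config.sets_per_trip:05d}"
                         for i in range(len(events))]
    by_sp = (assoc.groupby(["fob", "day", "species"])["biomass"].sum()
             .reset_index())
    merged = events.merge(by_sp, on=["fob", "day"], how="left")
    totals = merged.groupby("set_id")["biomass"].sum()
    events["true_catch"] = events["set_id"].map(totals).fillna(0.0)
    noise = rng_decl.lognormal(0.0, config.declaration_sigma, len(events))
    events["declared_catch"] = events["true_catch"] * noise
    events["sampled"] = rng_sample.random(len(events)) < config.sampled_fraction
    fi, di = events["fob"].to_numpy(int), events["day"].to_numpy(int)
    events["date"] = dates[di]
    events["lat"] = lat[fi, di]
    events["lon"] = lon[fi, di]
    sets = events[set_cols]

    landings = (sets.groupby("trip_id")["true_catch"].sum()
                .rename("landed_total").reset_index())

    sampled_ids = set(sets.loc[sets["sampled"], "set_id"])
    comp = merged[merged["set_id"].isin(sampled_ids) & (merged["biomass"] > 0)].copy()
    comp["proportion"] = comp["biomass"] / comp["set_id"].map(totals)
    samples = (comp[["set_id", "species", "proportion"]]
               .sort_values(["set_id", "species"]).reset_index(drop=True))
    return sets, landings, samples


def _grid_counts(buoy_days: pd.DataFrame) -> pd.DataFrame:
    """Monthly mean operational-buoy counts on a 1-degree grid."""
    df = buoy_days.copy()
    df["lat_min"] = np.floor(df["lat"]).astype(int)
    df["lon_min"] = np.floor(df["lon"]).astype(int)
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    per_day = (df.groupby(["year", "month", "lat_min", "lon_min", "date"])
               ["buoy_id"].nunique().rename("n").reset_index())
    month_days = (df.groupby(["year", "month"])["date"].nunique()
                  .rename("n_days"))
    out = (per_day.groupby(["year", "month", "lat_min", "lon_min"])["n"].sum()
           .reset_index())
    out = out.join(month_days, on=["year", "month"])
    out["mean_buoys"] = out["n"] / out["n_days"]
    return out[["year", "month", "lat_min", "lon_min", "mean_buoys"]]


def theoretical_occupancy(config: SimConfig, n_days: float = 2000.0,
                          dt: float = 0.05, burn_in: float = 100.0,
                          seed: Optional[int] = None) -> float:
    """Long-run expected fraction of objects above the detection threshold.

    A deliberately plain fixed-time-step re-simulation of the two-state
    dynamics, independent of :func:`simulate`'s interval machinery; used as
    an oracle in tests, not in the estimator.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_regions = len(config.regions)
    fobs_per_region = _split_even(config.n_fobs, n_regions)
    fob_offsets = np.concatenate([[0], np.cumsum(fobs_per_region)[:-1]])

    sp_region, sp_crt, sp_cat, sp_biomass = [], [], [], []
    for sp, spec in config.species.items():
        n_per_region = _split_even(spec.n_schools, n_regions)
        for ri in range(n_regions):
            cat = (config.cat_days if config.cat_days is not None
                   else 1.0 / (config.phi * fobs_per_region[ri]))
            sp_region += [ri] * n_per_region[ri]
            sp_crt += [spec.crt_days] * n_per_region[ri]
            sp_cat += [cat] * n_per_region[ri]
            sp_biomass += list(rng.lognormal(spec.biomass_meanlog,
                                             spec.biomass_sdlog,
                                             n_per_region[ri]))
    n_schools = len(sp_region)
    if n_schools == 0:
        return 0.0
    region = np.array(sp_region)
    crt = np.array(sp_crt)
    cat = np.array(sp_cat)
    biomass = np.array(sp_biomass)
    p_leave = 1.0 - np.exp(-dt / crt)
    p_join = 1.0 - np.exp(-dt / cat)

    p_assoc0 = crt / (crt + cat)
    associated = rng.random(n_schools) < p_assoc0
    fob = np.array([
        fob_offsets[r] + rng.integers(fobs_per_region[r]) for r in region])

    n_steps = int(round(n_days / dt))
    burn_steps = int(round(burn_in / dt))
    sample_every = max(1, int(round(1.0 / dt)))
    occ_sum, occ_n = 0.0, 0
    for step in range(n_steps):
        u = rng.random(n_schools)
        leaving = associated & (u < p_leave)
        joining = (~associated) & (u < p_join)
        if joining.any():
            idx = np.flatnonzero(joining)
            fob[idx] = [fob_offsets[region[i]] + rng.integers(fobs_per_region[region[i]])
                        for i in idx]
        associated = (associated & ~leaving) | joining
        if step >= burn_steps and step % sample_every == 0:
            load = np.zeros(config.n_fobs)
            np.add.at(load, fob[associated], biomass[associated])
            occ_sum += float((load >= config.detection_threshold).mean())
            occ_n += 1
    return occ_sum / occ_n if occ_n else 0.0
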