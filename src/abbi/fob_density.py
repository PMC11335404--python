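"""Per-stratum floating-object density (p-hat) under two data regimes.

Regime 1 (buoy tracks): daily positions of the echosounder buoys of a
single fleet. The daily count of distinct buoys per cell is averaged over
the quarter and scaled up by two multiplication factors — one for the
objects of other fleets, one for natural objects and debris.

Regime 2 (gridded counts): monthly 1°x1° averages of operational buoys
across all fleets. These are summed into the 10° cells, averaged over the
quarter's months, and scaled by the other-objects factor only (the grid
already spans all purse-seine fleets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strata import STRATUM_COLS, RegionSet, days_in_quarter, quarter_start

log = logging.getLogger(__name__)

TRACKS = "buoy_tracks"
GRID = "gridded_counts"


@dataclass(frozen=True)
class RaisingFactors:
    """Multiplicative corrections from one fleet's buoys to all floating objects.

    Both default to 1 and must be supplied by the user: their operational
    values are survey-specific calibration inputs, not constants of the
    method.
    """

    fleet_factor: float = 1.0
    other_objects_factor: float = 1.0

    def __post_init__(self):
        for name in ("fleet_factor", "other_objects_factor"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 1.0:
                raise ValueError(f"{name} must be finite and >= 1, got {v}")


def reduce_daily(tracks: pd.DataFrame, how: str = "last") -> pd.DataFrame:
    """Collapse multi-ping tracks to one position per buoy per day.

    ``how`` is one of 'last' (default), 'first' or 'mean'.
    """
    df = tracks.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()
    df = df.sort_values(["buoy_id", "timestamp"], kind="mergesort")
    g = df.groupby(["buoy_id", "date"], as_index=False)
    if how == "last":
        out = g.last()
    elif how == "first":
        out = g.first()
    elif how == "mean":
        out = g.agg(lat=("lat", "mean"), lon=("lon", "mean"))
    else:
        raise ValueError(f"unknown daily reduction: {how!r}")
    return out[["buoy_id", "date", "lat", "lon"]]


def _coverage_days(year: int, quarter: int, cov_min, cov_max) -> int:
    """Calendar days of the quarter lying inside the dataset's date coverage."""
    qs = quarter_start(year, quarter)
    qe = qs + pd.Timedelta(days=days_in_quarter(year, quarter) - 1)
    lo, hi = max(qs, cov_min), min(qe, cov_max)
    return max(0, int((hi - lo).days) + 1)


def estimate_p_from_tracks(tracks: pd.DataFrame, regions: RegionSet,
                           factors: RaisingFactors,
                           daily_reduction: str = "last") -> pd.DataFrame:
    """Track-regime p-hat per stratum.

    p-hat = (mean over the quarter's days of the count of distinct buoys in
    the cell that day) x fleet_factor x other_objects_factor. Days without
    a buoy in the cell count as zeros; the averaging window is the part of
    the quarter covered by the dataset as a whole. Strata with no buoy-days
    are missing from the output.
    """
    if len(tracks) == 0:
        log.warning("estimate_p_from_tracks: empty input, no estimates produced")
        return pd.DataFrame(columns=STRATUM_COLS + ["p_hat", "n_days", "source_regime"])
    daily = reduce_daily(tracks, how=daily_reduction)
    cov_min, cov_max = daily["date"].min(), daily["date"].max()
    assigned = regions.assign_frame(daily)
    if len(assigned) == 0:
        log.warning("estimate_p_from_tracks: no buoy-day falls inside the study area")
        return pd.DataFrame(columns=STRATUM_COLS + ["p_hat", "n_days", "source_regime"])
    per_day = (assigned.groupby(STRATUM_COLS + ["date"])["buoy_id"]
               .nunique().rename("n_buoys").reset_index())
    totals = per_day.groupby(STRATUM_COLS, as_index=False)["n_buoys"].sum()
    n_days = np.array([
        _coverage_days(y, q, cov_min, cov_max)
        for y, q in zip(totals["year"], totals["quarter"])
    ])
    scale = factors.fleet_factor * factors.other_objects_factor
    totals["p_hat"] = totals["n_buoys"] / n_days * scale
    totals["n_days"] = n_days
    totals["source_regime"] = TRACKS
    return totals.drop(columns="n_buoys")


def estimate_p_from_grid(counts: pd.DataFrame, regions: RegionSet,
                         factors: RaisingFactors) -> pd.DataFrame:
    """Grid-regime p-hat per stratum.

    Monthly 1° counts are summed over each 10° cell, averaged over the
    quarter's available months, and scaled by the other-objects factor.
    The fleet factor is not applied: the gridded counts already cover all
    fleets.
    """
    if len(counts) == 0:
        log.warning("estimate_p_from_grid: empty input, no estimates produced")
        return pd.DataFrame(columns=STRATUM_COLS + ["p_hat", "n_months", "source_regime"])
    df = counts.copy()
    # Assign 1° cells by their centre so edge cells land in a unique 10° cell.
    df["lat"] = df["lat_min"].astype(float) + 0.5
    df["lon"] = df["lon_min"].astype(float) + 0.5
    df["date"] = pd.to_datetime(dict(year=df["year"], month=df["month"], day=1))
    assigned = regions.assign_frame(df.drop(columns=["lat_min", "lon_min"]))
    if len(assigned) == 0:
        log.warning("estimate_p_from_grid: no 1° cell falls inside the study area")
        return pd.DataFrame(columns=STRATUM_COLS + ["p_hat", "n_months", "source_regime"])
    monthly = (assigned.groupby(STRATUM_COLS + ["month"], as_index=False)
               ["mean_buoys"].sum())
    out = (monthly.groupby(STRATUM_COLS)
           .agg(p_hat=("mean_buoys", "mean"), n_months=("month", "nunique"))
           .reset_index())
    short = out[out["n_months"] < 3]
    if len(short):
        log.info("estimate_p_from_grid: %d strata averaged over fewer than 3 months",
                 len(short))
    out["p_hat"] = out["p_hat"] * factors.other_objects_factor
    out["source_regime"] = GRID
    return out


def stitch_regimes(tracks_density: pd.DataFrame, grid_density: pd.DataFrame,
                   switch_date) -> pd.DataFrame:
    """Combine the two regimes into one series.

    Strata whose quarter starts before ``switch_date`` use the track
    regime, later ones the grid regime; where the preferred regime has no
    estimate, the other is used if available. Provenance is kept in
    ``source_regime``.
    """
    switch = pd.Timestamp(switch_date)
    cols = STRATUM_COLS + ["p_hat", "source_regime"]

    def _clean(df):
        if len(df) == 0:
            return pd.DataFrame(columns=cols)
        return df[cols].copy()

    t, g = _clean(tracks_density), _clean(grid_density)
    merged = t.merge(g, on=STRATUM_COLS, how="outer", suffixes=("_t", "_g"))
    qstarts = pd.Series([quarter_start(y, q) for y, q in
                         zip(merged["year"], merged["quarter"])])
    prefer_grid = (qstarts >= switch).to_numpy()
    has_t = merged["p_hat_t"].notna().to_numpy()
    has_g = merged["p_hat_g"].notna().to_numpy()
    use_grid = (prefer_grid & has_g) | (~prefer_grid & ~has_t & has_g)
    merged["p_hat"] = np.where(use_grid, merged["p_hat_g"], merged["p_hat_t"])
    merged["source_regime"] = np.where(use_grid, GRID, TRACKS)
    missing = ~(has_t | has_g)
    if missing.any():
        log.warning("stitch_regimes: %d strata covered by neither regime",
                    int(missing.sum()))
    return merged.loc[~missing, cols].reset_index(drop=True)
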