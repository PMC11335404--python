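"""Spatio-temporal stratification.

The study area is a set of named square cells (10 degrees a side by
default) crossed with calendar year-quarters. Every record that carries a
position and a date is assigned to exactly one stratum, or to none if it
falls outside the configured cells. Cell bounds are half-open
``[min, min + cell_size)`` so that points on shared edges belong to
exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Columns that jointly identify a stratum in every tabular output.
STRATUM_COLS = ["region_id", "lat_min", "lon_min", "year", "quarter"]


def quarter_of(date) -> int:
    """Calendar quarter of a date: Jan–Mar → 1, …, Oct–Dec → 4."""
    ts = pd.Timestamp(date)
    if pd.isna(ts):
        raise ValueError(f"invalid date: {date!r}")
    return (ts.month - 1) // 3 + 1


def quarter_start(year: int, quarter: int) -> pd.Timestamp:
    if quarter not in (1, 2, 3, 4):
        raise ValueError(f"quarter must be in 1..4, got {quarter}")
    return pd.Timestamp(year=int(year), month=3 * (quarter - 1) + 1, day=1)


def days_in_quarter(year: int, quarter: int) -> int:
    start = quarter_start(year, quarter)
    end = quarter_start(year + 1, 1) if quarter == 4 else quarter_start(year, quarter + 1)
    return int((end - start).days)


@dataclass(frozen=True)
class Region:
    """One square cell of the study area, identified by its lower-left corner."""

    region_id: str
    lat_min: float
    lon_min: float


@dataclass(frozen=True)
class StratumKey:
    """A region cell crossed with a year-quarter."""

    region_id: str
    lat_min: float
    lon_min: float
    year: int
    quarter: int

    def __post_init__(self):
        if self.quarter not in (1, 2, 3, 4):
            raise ValueError(f"quarter must be in 1..4, got {self.quarter}")
        if not (-90.0 <= self.lat_min <= 90.0):
            raise ValueError(f"lat_min out of range: {self.lat_min}")
        if not (-180.0 <= self.lon_min < 180.0):
            raise ValueError(f"lon_min out of range: {self.lon_min}")


class RegionSet:
    """The collection of disjoint cells composing the study area.

    Parameters
    ----------
    regions
        Iterable of ``Region`` (or ``(region_id, lat_min, lon_min)`` tuples).
    cell_size
        Cell edge length in degrees; the default matches a 10° x 10°
        stratification.
    """

    def __init__(self, regions: Iterable, cell_size: float = 10.0):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        parsed = []
        for r in regions:
            if not isinstance(r, Region):
                r = Region(str(r[0]), float(r[1]), float(r[2]))
            if not (-90.0 <= r.lat_min and r.lat_min + cell_size <= 90.0):
                raise ValueError(f"region {r.region_id}: latitude band outside [-90, 90]")
            if not (-180.0 <= r.lon_min < 180.0):
                raise ValueError(f"region {r.region_id}: lon_min outside [-180, 180)")
            parsed.append(r)
        if not parsed:
            raise ValueError("region set must contain at least one cell")
        corners = {(r.lat_min, r.lon_min) for r in parsed}
        if len(corners) != len(parsed):
            raise ValueError("region cells must be disjoint (duplicate corners found)")
        ids = {r.region_id for r in parsed}
        if len(ids) != len(parsed):
            raise ValueError("region ids must be unique")
        self.regions: Sequence[Region] = tuple(parsed)
        self.cell_size = float(cell_size)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)

    def region_of(self, lat: float, lon: float) -> Optional[Region]:
        """Cell containing a point (lower-inclusive, upper-exclusive), or None."""
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon < 360.0):
            raise ValueError(f"invalid coordinates: lat={lat}, lon={lon}")
        for r in self.regions:
            if (r.lat_min <= lat < r.lat_min + self.cell_size
                    and r.lon_min <= lon < r.lon_min + self.cell_size):
                return r
        return None

    def assign_stratum(self, lat: float, lon: float, date) -> Optional[StratumKey]:
        """Stratum containing a point-date, or None if outside the study area."""
        region = self.region_of(lat, lon)
        if region is None:
            return None
        ts = pd.Timestamp(date)
        if pd.isna(ts):
            raise ValueError(f"invalid date: {date!r}")
        return StratumKey(region.region_id, region.lat_min, region.lon_min,
                          int(ts.year), quarter_of(ts))

    def assign_frame(self, df: pd.DataFrame, lat_col: str = "lat",
                     lon_col: str = "lon", date_col: str = "date",
                     drop_outside: bool = True) -> pd.DataFrame:
        """Vectorised stratum assignment; adds the STRATUM_COLS columns.

        Rows outside every cell are dropped when ``drop_outside`` is true,
        otherwise kept with missing region columns.
        """
        out = df.copy()
        lat = out[lat_col].to_numpy(dtype=float)
        lon = out[lon_col].to_numpy(dtype=float)
        region_id = np.full(len(out), None, dtype=object)
        lat_min = np.full(len(out), np.nan)
        lon_min = np.full(len(out), np.nan)
        for r in self.regions:
            m = ((lat >= r.lat_min) & (lat < r.lat_min + self.cell_size)
                 & (lon >= r.lon_min) & (lon < r.lon_min + self.cell_size))
            region_id[m] = r.region_id
            lat_min[m] = r.lat_min
            lon_min[m] = r.lon_min
        dates = pd.to_datetime(out[date_col])
        out["region_id"] = region_id
        out["lat_min"] = lat_min
        out["lon_min"] = lon_min
        out["year"] = dates.dt.year.to_numpy()
        out["quarter"] = ((dates.dt.month - 1) // 3 + 1).to_numpy()
        if drop_outside:
            out = out[~pd.isna(out["region_id"])].reset_index(drop=True)
        return out

    @classmethod
    def from_config(cls, entries: Iterable[dict], cell_size: float = 10.0) -> "RegionSet":
        """Build from configuration entries ``{region_id, lat_min, lon_min}``."""
        return cls([(e["region_id"], e["lat_min"], e["lon_min"]) for e in entries],
                   cell_size=cell_size)


def default_region_set() -> RegionSet:
    """Five contiguous 10° cells in the western Indian Ocean.

    Illustrative defaults: the operational study-area polygons are a
    configuration concern and should be overridden for real analyses.
    """
    return RegionSet([
        ("Reg.1", 0.0, 50.0),
        ("Reg.2", -10.0, 40.0),
        ("Reg.3", -10.0, 50.0),
        ("Reg.4", -10.0, 60.0),
        ("Reg.5", -20.0, 50.0),
    ])
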