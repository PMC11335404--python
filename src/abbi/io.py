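"""Tabular I/O, structured run configuration, and the end-to-end pipeline.

All tables are headed CSV; dates are ISO-8601, coordinates decimal degrees
(WGS-84 implied). Readers validate schemas: a missing column is an error,
a malformed row is rejected with a line-numbered warning and the remaining
rows are kept.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .abbi_index import (area_average, associated_ratio, relative_index,
                         stratum_abbi, uncertainty)
from .assoc_biomass import (estimate_m, impute_composition_emm, level1_correct,
                            stratum_composition)
from .behaviour import (SpeciesBehaviour, cat_from_phi, default_registry,
                        registry_from_config)
from .fob_density import (RaisingFactors, estimate_p_from_grid,
                          estimate_p_from_tracks, stitch_regimes)
from .occupancy import (daily_fraction, impute_eta_binomial, occurrence_rate,
                        species_occupancy_table, stationarity_check,
                        stratum_occupancy, trim_colonization)
from .simulator import SimConfig, SimResult, SpeciesSim, simulate
from .strata import STRATUM_COLS, RegionSet, default_region_set

log = logging.getLogger(__name__)

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _parse_bool(v: str) -> bool:
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _parse_date(v: str):
    ts = pd.Timestamp(v)
    if pd.isna(ts):
        raise ValueError(f"not a date: {v!r}")
    return ts


SCHEMAS: Dict[str, Dict[str, object]] = {
    "buoy_tracks": {"buoy_id": str, "timestamp": _parse_date,
                    "lat": float, "lon": float},
    "gridded_counts": {"year": int, "month": int, "lat_min": float,
                       "lon_min": float, "mean_buoys": float},
    "sets": {"trip_id": str, "set_id": str, "date": _parse_date, "lat": float,
             "lon": float, "declared_catch": float, "sampled": _parse_bool},
    "landings": {"trip_id": str, "landed_total": float},
    "samples": {"set_id": str, "species": str, "proportion": float},
    "buoy_days": {"buoy_id": str, "date": _parse_date, "lat": float,
                  "lon": float, "present": _parse_bool,
                  "days_since_deployment": int},
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate one CSV against a named schema.

    Malformed rows are dropped with a warning carrying their file line
    number; a missing required column raises.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in spec if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} "
                         f"for schema {schema!r}")
    if len(raw) == 0:
        log.warning("%s: empty file", path)
        return pd.DataFrame({c: pd.Series(dtype=object) for c in spec})
    parsed: Dict[str, list] = {c: [] for c in spec}
    bad_lines = []
    for i, row in enumerate(raw.itertuples(index=False)):
        rec = {}
        try:
            for col, parser in spec.items():
                rec[col] = parser(getattr(row, col))
        except (ValueError, TypeError):
            bad_lines.append(i + 2)  # header is line 1
            continue
        for col in spec:
            parsed[col].append(rec[col])
    if bad_lines:
        log.warning("%s: rejected %d malformed row(s) at line(s) %s",
                    path, len(bad_lines), bad_lines[:10])
    out = pd.DataFrame(parsed)
    log.info("%s: read %d row(s) [%s]", path, len(out), schema)
    return out


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_sim_tables(result: SimResult, outdir) -> Dict[str, Path]:
    """Write a simulation's five input tables plus the truth table."""
    outdir = Path(outdir)
    paths = {}
    buoy_tracks = result.buoy_days.rename(columns={"date": "timestamp"})[
        ["buoy_id", "timestamp", "lat", "lon"]]
    tables = {
        "buoy_tracks": buoy_tracks,
        "gridded_counts": result.gridded_counts,
        "sets": result.sets.drop(columns=["true_catch"]),
        "landings": result.landings,
        "samples": result.samples,
        "buoy_days": result.buoy_days,
        "truth": result.truth,
    }
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        write_table(df, p)
        paths[name] = p
    return paths


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    regions: RegionSet = field(default_factory=default_region_set)
    min_sets: int = 20
    min_buoys: int = 30
    detection_threshold: float = 1.0
    raising_factors: RaisingFactors = field(default_factory=RaisingFactors)
    phi_grid: Sequence[float] = (2e-5, 6e-5)
    crt_registry: Dict[str, SpeciesBehaviour] = field(default_factory=default_registry)
    baseline: Optional[Tuple[int, int]] = None
    density_regime: str = "auto"  # tracks | grid | auto
    switch_date: Optional[str] = None
    seed: int = 0
    uncertainty_method: str = "sem"
    n_boot: int = 1000
    inputs: Optional[Dict[str, str]] = None     # schema name -> csv path
    simulate: Optional[SimConfig] = None
    output_dir: Optional[str] = None

    def __post_init__(self):
        if len(self.phi_grid) == 0:
            raise ValueError("phi grid must be non-empty")
        if any(p <= 0 for p in self.phi_grid):
            raise ValueError("phi values must be positive")
        if self.min_sets <= 0 or self.min_buoys <= 0 or self.detection_threshold < 0:
            raise ValueError("thresholds must be positive")
        if self.density_regime not in ("tracks", "grid", "auto"):
            raise ValueError(f"unknown density regime {self.density_regime!r}")
        if self.inputs is None and self.simulate is None:
            raise ValueError("either input paths or a simulation config is required")


def sim_config_from_dict(d: dict, regions: Optional[RegionSet] = None) -> SimConfig:
    d = dict(d)
    if "species" in d:
        d["species"] = {
            sp: SpeciesSim(**v) for sp, v in d["species"].items()}
    if regions is not None and "regions" not in d:
        d["regions"] = regions
    return SimConfig(**d)


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw: Dict[str, object] = {}
    regions = (RegionSet.from_config(raw["regions"],
                                     cell_size=raw.get("cell_size", 10.0))
               if "regions" in raw else default_region_set())
    kw["regions"] = regions
    thr = raw.get("thresholds", {})
    kw["min_sets"] = thr.get("min_sets", 20)
    kw["min_buoys"] = thr.get("min_buoys", 30)
    kw["detection_threshold"] = thr.get("detection", 1.0)
    rf = raw.get("raising_factors", {})
    kw["raising_factors"] = RaisingFactors(
        fleet_factor=rf.get("fleet_factor", 1.0),
        other_objects_factor=rf.get("other_objects_factor", 1.0))
    if "phi_grid" in raw:
        kw["phi_grid"] = [float(p) for p in raw["phi_grid"]]
    if "crt_registry" in raw:
        kw["crt_registry"] = registry_from_config(raw["crt_registry"])
    if "baseline" in raw:
        kw["baseline"] = (int(raw["baseline"]["year"]),
                          int(raw["baseline"]["quarter"]))
    for key in ("density_regime", "switch_date", "seed", "uncertainty_method",
                "n_boot", "inputs", "output_dir"):
        if key in raw:
            kw[key] = raw[key]
    if "simulate" in raw:
        kw["simulate"] = sim_config_from_dict(raw["simulate"], regions=regions)
    return RunConfig(**kw)


def config_hash(config: RunConfig) -> str:
    """Stable digest of a run configuration (for the manifest)."""

    def encode(obj):
        if isinstance(obj, RegionSet):
            return {"cell_size": obj.cell_size,
                    "regions": [(r.region_id, r.lat_min, r.lon_min) for r in obj]}
        if isinstance(obj, (RaisingFactors, SpeciesBehaviour, SimConfig, SpeciesSim)):
            return {k: encode(v) for k, v in vars(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    payload = {k: v for k, v in vars(config).items() if k != "output_dir"}
    blob = json.dumps(encode(payload), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err
        return wrapped
    return deco


def _load_inputs(config: RunConfig) -> Dict[str, pd.DataFrame]:
    if config.simulate is not None:
        result = simulate(config.simulate)
        tracks = result.buoy_days.rename(columns={"date": "timestamp"})[
            ["buoy_id", "timestamp", "lat", "lon"]]
        return {"buoy_tracks": tracks,
                "gridded_counts": result.gridded_counts,
                "sets": result.sets.drop(columns=["true_catch"]),
                "landings": result.landings,
                "samples": result.samples,
                "buoy_days": result.buoy_days,
                "truth": result.truth}
    tables = {}
    for name, path in config.inputs.items():
        if name in SCHEMAS:
            tables[name] = read_table(path, name)
    return tables


def _density(config: RunConfig, tables) -> pd.DataFrame:
    have_tracks = "buoy_tracks" in tables and len(tables["buoy_tracks"]) > 0
    have_grid = "gridded_counts" in tables and len(tables["gridded_counts"]) > 0
    regime = config.density_regime
    if regime == "tracks" or (regime == "auto" and not have_grid):
        return estimate_p_from_tracks(tables["buoy_tracks"], config.regions,
                                      config.raising_factors)
    if regime == "grid" or (regime == "auto" and not have_tracks):
        return estimate_p_from_grid(tables["gridded_counts"], config.regions,
                                    config.raising_factors)
    if config.switch_date is None:
        if regime == "auto":
            log.info("both density regimes available and no switch_date: "
                     "using buoy tracks")
            return estimate_p_from_tracks(tables["buoy_tracks"], config.regions,
                                          config.raising_factors)
        raise ValueError("both density regimes supplied: a switch_date is required")
    t = estimate_p_from_tracks(tables["buoy_tracks"], config.regions,
                               config.raising_factors)
    g = estimate_p_from_grid(tables["gridded_counts"], config.regions,
                             config.raising_factors)
    return stitch_regimes(t, g, config.switch_date)


def run_pipeline(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Execute density -> biomass -> occupancy -> behaviour -> index.

    Returns all intermediate and final tables; writes them (plus a run
    manifest) under ``config.output_dir`` when set. Fixed config and inputs
    give byte-identical outputs.
    """
    tables = _stage("inputs")(_load_inputs)(config)

    density = _stage("density")(_density)(config, tables)

    @_stage("biomass")
    def _biomass():
        corrected = level1_correct(tables["sets"], tables["landings"])
        comp = stratum_composition(corrected, tables["samples"], config.regions,
                                   min_sets=config.min_sets)
        comp = impute_composition_emm(comp)
        m_hat = estimate_m(corrected, comp, config.regions,
                           min_sets=config.min_sets)
        return corrected, comp, m_hat

    corrected_sets, composition, m_hat = _biomass()

    @_stage("occupancy")
    def _occupancy():
        trimmed = trim_colonization(tables["buoy_days"])
        daily = daily_fraction(trimmed, config.regions,
                               min_buoys=config.min_buoys)
        f_hat = stratum_occupancy(daily)
        eta = occurrence_rate(corrected_sets, tables["samples"], config.regions,
                              threshold=config.detection_threshold,
                              min_sets=config.min_sets)
        eta = impute_eta_binomial(eta)
        f_i = species_occupancy_table(f_hat, eta)
        stationarity = stationarity_check(daily)
        return daily, f_hat, eta, f_i, stationarity

    daily, f_hat, eta, f_i, stationarity = _occupancy()

    @_stage("index")
    def _index():
        inputs = (m_hat.merge(f_i[STRATUM_COLS + ["species", "f_hat",
                                                  "eta_hat", "f_i"]],
                              on=STRATUM_COLS + ["species"], how="inner")
                  .merge(density[STRATUM_COLS + ["p_hat", "source_regime"]],
                         on=STRATUM_COLS, how="inner"))
        unknown = set(inputs["species"]) - set(config.crt_registry)
        if unknown:
            raise ValueError(f"species missing from the CRT registry: "
                             f"{sorted(unknown)}")
        inputs["crt"] = inputs["species"].map(
            {sp: b.crt_mean for sp, b in config.crt_registry.items()})
        per_phi_est, per_phi_abs, per_phi_rel, per_phi_ratio, per_phi_se = \
            [], [], [], [], []
        for phi in config.phi_grid:
            work = inputs.copy()
            work["cat"] = cat_from_phi(phi, work["p_hat"].to_numpy())
            est = stratum_abbi(work)
            abs_series = area_average(est)
            rel_series = relative_index(abs_series, baseline=config.baseline)
            ratio = associated_ratio(est)
            se = uncertainty(est, method=config.uncertainty_method,
                             n_boot=config.n_boot, seed=config.seed)
            for frame in (est, abs_series, rel_series, ratio, se):
                frame["phi"] = phi
            per_phi_est.append(est)
            per_phi_abs.append(abs_series)
            per_phi_rel.append(rel_series)
            per_phi_ratio.append(ratio)
            per_phi_se.append(se)
        return (pd.concat(per_phi_est, ignore_index=True),
                pd.concat(per_phi_abs, ignore_index=True),
                pd.concat(per_phi_rel, ignore_index=True),
                pd.concat(per_phi_ratio, ignore_index=True),
                pd.concat(per_phi_se, ignore_index=True))

    estimates, absolute, relative, ratio, se = _index()

    out = {
        "density": density,
        "m_hat": m_hat,
        "composition": composition,
        "daily_occupancy": daily,
        "f_hat": f_hat,
        "eta": eta,
        "f_i": f_i,
        "stationarity": stationarity,
        "stratum_estimates": estimates,
        "index_absolute": absolute,
        "index_relative": relative,
        "associated_ratio": ratio,
        "index_se": se,
    }
    if "truth" in tables:
        out["truth"] = tables["truth"]

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            write_table(df, outdir / f"{name}.csv")
        manifest = {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "abbi_version": __version__,
            "phi_grid": list(map(float, config.phi_grid)),
            "row_counts": {k: int(len(v)) for k, v in sorted(out.items())},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return out
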