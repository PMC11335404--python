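"""Assembly of the Associative Behaviour-Based abundance Index.

Per stratum and species, the associated component of the population is

    X_a = m_hat * f_i * p_hat

(mean associated biomass per object x fraction of objects holding the
species x number of objects), and renewal of residence/absence cycles ties
the associated share to the behavioural time scales,

    X_a / N = CRT / (CRT + CAT),

so the total and unassociated components follow as

    N = X_a * (1 + CAT/CRT),      X_u = X_a * CAT/CRT.

Stratum estimates are averaged (unweighted) over the available strata of
each quarter into an abundance per cell, optionally normalised to a
baseline quarter, with a between-strata standard error or a stratum
bootstrap for uncertainty.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .behaviour import SensitivityGrid, cat_from_phi
from .strata import STRATUM_COLS

log = logging.getLogger(__name__)

QUARTER_COLS = ["species", "year", "quarter"]


def stratum_abbi(inputs: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum abundance estimates from assembled inputs.

    ``inputs`` must carry ``m_hat``, ``f_i``, ``p_hat``, ``crt`` and
    ``cat`` per stratum and species. ``n_total = x_a + x_u`` holds exactly
    by construction.
    """
    req = ["m_hat", "f_i", "p_hat", "crt", "cat"]
    missing = [c for c in req if c not in inputs.columns]
    if missing:
        raise ValueError(f"stratum inputs lack columns: {missing}")
    if (inputs["crt"] <= 0).any():
        raise ValueError("crt must be positive")
    if (inputs[["m_hat", "f_i", "p_hat", "cat"]] < 0).to_numpy().any():
        raise ValueError("m_hat, f_i, p_hat and cat must be non-negative")
    out = inputs.copy()
    out["x_a"] = out["m_hat"] * out["f_i"] * out["p_hat"]
    out["x_u"] = out["x_a"] * (out["cat"] / out["crt"])
    out["n_total"] = out["x_a"] + out["x_u"]
    return out


def area_average(estimates: pd.DataFrame) -> pd.DataFrame:
    """Quarterly index: unweighted mean over available strata, per species.

    Returns abundance per cell with the contributing stratum count and the
    between-strata standard error of the mean (missing for single-stratum
    quarters).
    """
    if len(estimates) == 0:
        raise ValueError("no stratum estimates to average")
    g = estimates.groupby(QUARTER_COLS)
    out = g.agg(n_total=("n_total", "mean"),
                x_a=("x_a", "mean"),
                x_u=("x_u", "mean"),
                n_strata=("n_total", "size"),
                sd=("n_total", "std")).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n_strata"])
    return out.drop(columns="sd").sort_values(QUARTER_COLS).reset_index(drop=True)


def _first_quarter(series: pd.DataFrame) -> Tuple[int, int]:
    ordered = series.sort_values(["year", "quarter"])
    return int(ordered["year"].iloc[0]), int(ordered["quarter"].iloc[0])


def relative_index(series: pd.DataFrame,
                   baseline: Optional[Tuple[int, int]] = None) -> pd.DataFrame:
    """Normalise an absolute series to a baseline quarter (value 1 there).

    ``baseline`` is ``(year, quarter)``; by default the chronologically
    first quarter available for each species.
    """
    frames = []
    for sp, grp in series.groupby("species"):
        base = baseline if baseline is not None else _first_quarter(grp)
        sel = grp[(grp["year"] == base[0]) & (grp["quarter"] == base[1])]
        if len(sel) == 0:
            raise ValueError(f"baseline quarter {base} missing for species {sp!r}")
        ref = float(sel["n_total"].iloc[0])
        if not ref > 0:
            raise ValueError(f"baseline abundance for {sp!r} is not positive")
        out = grp.copy()
        out["relative"] = out["n_total"] / ref
        out["baseline_year"], out["baseline_quarter"] = base
        frames.append(out)
    return (pd.concat(frames, ignore_index=True)
            .sort_values(QUARTER_COLS).reset_index(drop=True))


def associated_ratio(estimates: pd.DataFrame) -> pd.DataFrame:
    """Quarterly ratio of mean associated biomass to mean total biomass."""
    g = estimates.groupby(QUARTER_COLS)
    out = g.agg(x_a=("x_a", "mean"), n_total=("n_total", "mean"),
                n_strata=("n_total", "size")).reset_index()
    if (out["n_total"] <= 0).any():
        raise ValueError("associated_ratio undefined for non-positive totals")
    out["ratio"] = out["x_a"] / out["n_total"]
    return out.sort_values(QUARTER_COLS).reset_index(drop=True)


def uncertainty(estimates: pd.DataFrame, method: str = "sem",
                n_boot: int = 1000, seed: Optional[int] = None) -> pd.DataFrame:
    """Per-quarter standard error of the area-averaged total abundance.

    ``method='sem'`` uses the between-strata standard error of the mean;
    ``method='bootstrap'`` resamples strata with replacement (``n_boot``
    replicates, seeded). Single-stratum quarters report a missing se.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for key, grp in estimates.groupby(QUARTER_COLS):
        vals = grp["n_total"].to_numpy(dtype=float)
        rec = dict(zip(QUARTER_COLS, key))
        rec["n_strata"] = len(vals)
        if len(vals) < 2:
            rec["se"] = np.nan
        elif method == "sem":
            rec["se"] = vals.std(ddof=1) / np.sqrt(len(vals))
        elif method == "bootstrap":
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            rec["se"] = vals[idx].mean(axis=1).std(ddof=1)
        else:
            raise ValueError(f"unknown uncertainty method {method!r}")
        rows.append(rec)
    return pd.DataFrame(rows).sort_values(QUARTER_COLS).reset_index(drop=True)


def sensitivity_run(inputs: pd.DataFrame, grid: SensitivityGrid,
                    baseline: Optional[Tuple[int, int]] = None) -> Dict[str, pd.DataFrame]:
    """Re-run the index over a grid of phi (and optionally CRT) values.

    ``inputs`` carries ``m_hat``, ``f_i``, ``p_hat`` and ``crt`` per
    stratum/species; the absence-time scale is recomputed per grid point
    through the CAT model, never through a hand-simplified formula, so the
    CAT sub-model stays swappable. Returns absolute and relative series in
    long form plus a per-species summary of the maximum spread of the
    relative series across phi.
    """
    crt_grid: Sequence[Optional[float]] = (
        list(grid.crt_values) if grid.crt_values is not None else [None])
    absolutes, relatives = [], []
    for phi in grid.phi_values:
        for crt_override in crt_grid:
            work = inputs.copy()
            if crt_override is not None:
                work["crt"] = float(crt_override)
            work["cat"] = cat_from_phi(phi, work["p_hat"].to_numpy())
            est = stratum_abbi(work)
            abs_series = area_average(est)
            rel_series = relative_index(abs_series, baseline=baseline)
            for frame in (abs_series, rel_series):
                frame["phi"] = phi
                frame["crt_override"] = (np.nan if crt_override is None
                                         else crt_override)
            absolutes.append(abs_series)
            relatives.append(rel_series)
    absolute = pd.concat(absolutes, ignore_index=True)
    relative = pd.concat(relatives, ignore_index=True)

    spread = (relative.groupby(QUARTER_COLS + ["crt_override"], dropna=False)["relative"]
              .agg(lambda v: v.max() - v.min()).reset_index(name="phi_spread"))
    summary = (spread.groupby("species")["phi_spread"].max()
               .reset_index(name="max_relative_divergence_across_phi"))
    return {"absolute": absolute, "relative": relative, "summary": summary}
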