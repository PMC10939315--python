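"""The FLP-uptake rate chain: slope fit, clearance, grazing, turnover.

The estimator is the classic fluorescently-labeled-prey linear-uptake
model: plot the pooled mean number of FLP visible per grazer against
incubation time; the ordinary-least-squares slope is the per-grazer FLP
uptake in FLP grazer^-1 min^-1.  From there,

    hourly uptake   = 60 * slope                       (FLP grazer^-1 hr^-1)
    clearance rate  = hourly uptake / FLP ml^-1 at T0  (mL grazer^-1 hr^-1)
    specific rate   = clearance * prokaryotes ml^-1    (prey grazer^-1 hr^-1)
    grazing rate    = specific * eukaryotes ml^-1      (cells ml^-1 hr^-1)
    daily rate      = 24 * grazing rate                (cells ml^-1 day^-1)
    turnover % /day = 100 * daily rate / prokaryotes ml^-1

Exclusion rules:

* IGT experiments drop their final (Tf) timepoint before fitting -- grazer
  abundance collapses at Tf in pressurized chambers (bottle effects), which
  would corrupt the slope.
* A fitted slope <= 0 means grazing was below detection: every downstream
  rate is reported as zero and flagged, and flagged assays are excluded
  from group means (though they remain in exports as zeros).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (Constants, DEFAULT_CONSTANTS, GrazingExperiment,
                      GrazingRates, effective_prey_conc)
from .microscopy import mean_flp_per_grazer

__all__ = ["SlopeFit", "FitError", "fit_uptake_slope", "pooled_uptake_series",
           "rate_chain", "rates_from_clearance", "rates_table",
           "summarize", "summarize_abundance", "GROUPINGS"]

logger = logging.getLogger(__name__)


class FitError(ValueError):
    """Too few usable timepoints to fit an uptake slope."""


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of pooled mean FLP per grazer versus time (minutes)."""

    slope: float                 # FLP grazer^-1 min^-1
    intercept: float             # FLP grazer^-1
    stderr: float                # slope standard error, same units as slope
    n_points: int
    dropped_final: bool = False


def pooled_uptake_series(exp: GrazingExperiment,
                         drop_final: bool | None = None) -> pd.DataFrame:
    """Per-time pooled mean FLP per grazer for one experiment.

    ``drop_final`` defaults to True for IGT experiments (the Tf exclusion
    rule) and False otherwise.  Times where no replicate counted a grazer
    are dropped with a logged warning rather than imputed.
    """
    if drop_final is None:
        drop_final = exp.approach == "igt"
    tps = [tp for tp in exp.timepoints if not (drop_final and tp.is_final)]
    rows = []
    for t in sorted({tp.time_min for tp in tps}):
        at_t = [tp for tp in tps if tp.time_min == t]
        try:
            pooled = mean_flp_per_grazer(at_t)
        except ZeroDivisionError:
            logger.warning("%s: no grazers counted at t=%g min; dropped",
                           exp.experiment_id, t)
            continue
        rows.append({"time_min": t, "mean_flp_per_grazer": pooled.mean,
                     "sem": pooled.sem, "n_grazers": pooled.n_grazers})
    return pd.DataFrame(rows,
                        columns=["time_min", "mean_flp_per_grazer",
                                 "sem", "n_grazers"])


def fit_uptake_slope(exp: GrazingExperiment) -> SlopeFit:
    """Fit the uptake slope (FLP grazer^-1 min^-1) for one experiment.

    Unweighted OLS on the pooled per-timepoint means, intercept free.  For
    IGT experiments the final timepoint is removed first.  Raises
    :class:`FitError` if fewer than two usable timepoints remain.
    """
    drop_final = exp.approach == "igt"
    series = pooled_uptake_series(exp, drop_final=drop_final)
    if len(series) < 2:
        raise FitError(
            f"{exp.experiment_id}: {len(series)} usable timepoint(s); "
            "need at least 2 to fit a slope")
    x = series["time_min"].to_numpy()
    y = series["mean_flp_per_grazer"].to_numpy()
    if np.allclose(y, y[0]):
        # linregress stderr is undefined for an exactly flat series
        return SlopeFit(slope=0.0, intercept=float(y[0]), stderr=0.0,
                        n_points=len(series), dropped_final=drop_final)
    res = stats.linregress(x, y)
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    stderr=float(res.stderr), n_points=len(series),
                    dropped_final=drop_final)


def _below_detection(slope: float, stderr: float,
                     source: str) -> GrazingRates:
    return GrazingRates(
        slope_flp_per_grazer_min=slope, hourly_uptake=0.0,
        clearance_ml_per_grazer_hr=0.0, specific_grazing=0.0,
        grazing_rate_hr=0.0, grazing_rate_day=0.0, turnover_pct_day=0.0,
        below_detection=True, slope_stderr=stderr, prey_conc_source=source)


def rate_chain(fit: SlopeFit, exp: GrazingExperiment,
               constants: Constants = DEFAULT_CONSTANTS) -> GrazingRates:
    """Run the full rate chain from a fitted slope.

    A slope <= 0 (a flat series carries no evidence of grazing either)
    trips the below-detection gate: rates are zeroed and flagged.
    """
    prey = effective_prey_conc(exp, constants)
    if fit.slope <= 0:
        return _below_detection(fit.slope, fit.stderr, prey.source)
    if exp.flp_conc_t0 is None or exp.flp_conc_t0 <= 0:
        raise ValueError(
            f"{exp.experiment_id}: positive flp_conc_t0 required for the "
            "clearance rate")
    hourly = 60.0 * fit.slope
    clearance = hourly / exp.flp_conc_t0
    rates = rates_from_clearance(clearance, exp, constants)
    return GrazingRates(
        slope_flp_per_grazer_min=fit.slope, hourly_uptake=hourly,
        clearance_ml_per_grazer_hr=clearance,
        specific_grazing=rates.specific_grazing,
        grazing_rate_hr=rates.grazing_rate_hr,
        grazing_rate_day=rates.grazing_rate_day,
        turnover_pct_day=rates.turnover_pct_day,
        below_detection=False, slope_stderr=fit.stderr,
        prey_conc_source=prey.source)


def rates_from_clearance(clearance_ml_hr: float, exp: GrazingExperiment,
                         constants: Constants = DEFAULT_CONSTANTS,
                         ) -> GrazingRates:
    """Rate chain downstream of a known clearance rate.

    Used when the clearance is available directly (e.g. auditing published
    values) rather than via a slope fit; the slope and hourly uptake are
    back-filled from the FLP dose when known.
    """
    prey = effective_prey_conc(exp, constants)
    if clearance_ml_hr <= 0:
        return _below_detection(math.nan, math.nan, prey.source)
    if prey.value == 0:
        raise ZeroDivisionError(
            f"{exp.experiment_id}: turnover undefined with zero prey "
            "concentration and positive clearance")
    specific = clearance_ml_hr * prey.value
    rate_hr = specific * exp.euk_cells_ml
    rate_day = 24.0 * rate_hr
    turnover = 100.0 * rate_day / prey.value
    if exp.flp_conc_t0:
        hourly = clearance_ml_hr * exp.flp_conc_t0
        slope = hourly / 60.0
    else:
        hourly, slope = math.nan, math.nan
    return GrazingRates(
        slope_flp_per_grazer_min=slope,
        hourly_uptake=hourly if not math.isnan(hourly) else 0.0,
        clearance_ml_per_grazer_hr=clearance_ml_hr,
        specific_grazing=specific, grazing_rate_hr=rate_hr,
        grazing_rate_day=rate_day, turnover_pct_day=turnover,
        below_detection=False, slope_stderr=math.nan,
        prey_conc_source=prey.source)


_RATE_COLUMNS = [
    "slope_flp_per_grazer_min", "slope_stderr", "hourly_uptake",
    "clearance_ml_per_grazer_hr", "specific_grazing", "grazing_rate_hr",
    "grazing_rate_day", "turnover_pct_day", "below_detection",
    "prey_conc_source",
]


def rates_table(experiments: Sequence[GrazingExperiment],
                constants: Constants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Fit and chain every experiment; one row per experiment.

    Experiments whose slope cannot be fitted (too few usable timepoints)
    are skipped with a warning.
    """
    rows = []
    for exp in experiments:
        try:
            fit = fit_uptake_slope(exp)
        except FitError as err:
            logger.warning("skipping: %s", err)
            continue
        rates = rate_chain(fit, exp, constants)
        prey = effective_prey_conc(exp, constants)
        row = {
            "experiment_id": exp.experiment_id,
            "vent_field": exp.vent_field, "site": exp.site,
            "habitat": exp.habitat, "approach": exp.approach,
            "temperature_C": exp.temperature_c,
            "euk_cells_ml": exp.euk_cells_ml,
            "prok_cells_ml_effective": prey.value,
        }
        row.update({c: getattr(rates, c) for c in _RATE_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


#: Supported grouping keys -> column builder.
GROUPINGS = {
    "habitat": lambda df: df["habitat"],
    "vent_nonvent": lambda df: np.where(df["habitat"] == "vent",
                                        "vent", "nonvent"),
    "field": lambda df: df["vent_field"],
    "approach": lambda df: df["approach"],
    "habitat_field": lambda df: df["vent_field"].str.cat(
        df["habitat"], sep=":"),
}


def summarize(df: pd.DataFrame, by: str, value: str = "grazing_rate_hr",
              vent_only: bool = False) -> pd.DataFrame:
    """Group summaries of a rate column under the detection convention.

    Means, minima, and maxima are computed over detected (non-flagged)
    assays only; below-detection assays contribute to ``n_below_detection``
    but never to the statistics.  Groups with no detected assay report NaN,
    not zero.  Every experiment row counts once -- repeated samplings of
    one physical fluid are deliberately not deduplicated.
    """
    if by not in GROUPINGS:
        raise KeyError(f"unknown grouping {by!r}; choose from {list(GROUPINGS)}")
    work = df[df["habitat"] == "vent"].copy() if vent_only else df.copy()
    work["_group"] = GROUPINGS[by](work)
    out = []
    for key, grp in work.groupby("_group", sort=True):
        detected = grp[~grp["below_detection"]]
        vals = detected[value].dropna()
        out.append({
            "group": key, "n": len(grp), "n_detected": len(vals),
            "n_below_detection": int(grp["below_detection"].sum()),
            "mean": vals.mean() if len(vals) else math.nan,
            "min": vals.min() if len(vals) else math.nan,
            "max": vals.max() if len(vals) else math.nan,
        })
    return pd.DataFrame(out)


def summarize_abundance(df: pd.DataFrame, by: str,
                        value: str = "euk_cells_ml",
                        vent_only: bool = False) -> pd.DataFrame:
    """Group mean/min/max of an abundance column over all rows with a value.

    Unlike :func:`summarize`, below-detection assays are included (their
    abundances are real measurements); uncountable entries (NaN) are not.
    """
    if by not in GROUPINGS:
        raise KeyError(f"unknown grouping {by!r}; choose from {list(GROUPINGS)}")
    work = df[df["habitat"] == "vent"].copy() if vent_only else df.copy()
    work["_group"] = GROUPINGS[by](work)
    agg = (work.groupby("_group")[value]
           .agg(n="count", mean="mean", min="min", max="max")
           .reset_index().rename(columns={"_group": "group"}))
    return agg
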