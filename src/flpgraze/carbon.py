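"""Biovolume, cell carbon, population biomass, and consumption budgets.

Protistan cells are treated as prolate spheroids: biovolume
V = (pi/6) * d^2 * h, with h the longest cell dimension and d the cross
section of h (both um).  Carbon per cell follows the mixed-assemblage
(diatom-free) power law pg C cell^-1 = 0.216 * V^0.939.  Because the
exponent is below one the law is concave: converting the mean biovolume
always yields at least the mean of per-cell conversions, so the two
population conventions are distinct and both are exposed (per-cell
averaging is the default).

The consumption budget converts grazing rates into prey-carbon currency at
86 fg C per prokaryotic cell and compares the result against published
bounds on chemosynthetic primary production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Constants, DEFAULT_CONSTANTS, convert_rate_to_daily_carbon

__all__ = ["CellMorphometry", "CarbonEstimate", "CarbonBudget", "biovolume",
           "carbon_per_cell", "population_biomass", "carbon_factor",
           "biomass_bracket", "consumption_budget"]


@dataclass(frozen=True)
class CellMorphometry:
    """Linear dimensions of one measured cell (um)."""

    cell_id: str
    h_um: float     # longest cell dimension
    d_um: float     # cross section of h
    habitat: str = "vent"

    def __post_init__(self) -> None:
        if not (self.h_um >= self.d_um > 0):
            raise ValueError("cell dimensions must satisfy h >= d > 0")


@dataclass(frozen=True)
class CarbonEstimate:
    """Biovolume and carbon of one cell, optionally scaled to a population."""

    biovolume_um3: float
    pg_c_per_cell: float
    population_biomass_ug_l: float | None = None


def biovolume(m: CellMorphometry) -> float:
    """Prolate-spheroid biovolume (um^3): (pi/6) * d^2 * h."""
    return (math.pi / 6.0) * m.d_um ** 2 * m.h_um


def carbon_per_cell(biovolume_um3: float,
                    constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Carbon content of a cell (pg C) from its biovolume (um^3)."""
    if biovolume_um3 <= 0:
        raise ValueError("biovolume must be positive")
    return constants.allometry_a * biovolume_um3 ** constants.allometry_b


def population_biomass(pg_c_per_cell: float, euk_cells_ml: float) -> float:
    """Population biomass (ug C L^-1) = pg C cell^-1 x cells ml^-1 x 1e-3."""
    if pg_c_per_cell < 0 or euk_cells_ml < 0:
        raise ValueError("inputs must be >= 0")
    return pg_c_per_cell * euk_cells_ml * 1e-3


def carbon_factor(cells: Sequence[CellMorphometry],
                  constants: Constants = DEFAULT_CONSTANTS,
                  method: str = "per_cell") -> float:
    """Population carbon conversion factor (pg C cell^-1) from morphometry.

    ``per_cell`` (default) converts every cell and averages the carbon
    values; ``mean_volume`` converts the mean biovolume.  The concave power
    law guarantees per_cell <= mean_volume for any sample.
    """
    if not cells:
        raise ValueError("no cells supplied")
    vols = np.array([biovolume(m) for m in cells])
    if method == "per_cell":
        return float(np.mean([carbon_per_cell(v, constants) for v in vols]))
    if method == "mean_volume":
        return carbon_per_cell(float(vols.mean()), constants)
    raise ValueError(f"unknown method {method!r}")


def biomass_bracket(abundance_mean: float, abundance_min: float,
                    abundance_max: float, pg_c_per_cell: float,
                    ) -> dict[str, float]:
    """Mean/min/max population biomass (ug C L^-1) for one group.

    The bracket applies the group's single carbon factor to the group's
    abundance statistics -- the convention that reproduces published
    non-vent biomass brackets.
    """
    return {
        "mean": population_biomass(pg_c_per_cell, abundance_mean),
        "min": population_biomass(pg_c_per_cell, abundance_min),
        "max": population_biomass(pg_c_per_cell, abundance_max),
    }


@dataclass(frozen=True)
class CarbonBudget:
    """Prey-carbon consumption for one group of detected assays.

    All statistics are over detected assays only.  ``fraction_of_pp`` is a
    (vs-max, vs-min) pair against the primary-production bounds -- never a
    single number, because production is only known as a range.
    """

    group_key: str
    n_detected: int
    consumption_pg_c_ml_hr: dict[str, float]      # mean/min/max
    consumption_ug_c_l_day: dict[str, float]      # mean/min/max
    clearance_pg_c_per_grazer: dict[str, float]   # mean/min/max
    fraction_of_pp: tuple[float, float] | None    # (vs pp_max, vs pp_min)


def _stats(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {"mean": math.nan, "min": math.nan, "max": math.nan}
    return {"mean": float(values.mean()), "min": float(values.min()),
            "max": float(values.max())}


def consumption_budget(rates: pd.DataFrame, group_key: str = "all",
                       constants: Constants = DEFAULT_CONSTANTS,
                       ) -> CarbonBudget:
    """Carbon-consumption budget for a set of experiment rate rows.

    Expects the ``rates_table`` columns ``grazing_rate_hr``,
    ``specific_grazing``, and ``below_detection``.  Hourly consumption is
    the grazing rate x 86 fg C in pg C ml^-1 hr^-1; daily consumption
    converts each assay to ug C L^-1 day^-1 then aggregates; per-grazer
    clearance converts the specific grazing rate.  An empty detected set
    yields NaN statistics and no production fraction.
    """
    detected = rates[~rates["below_detection"]]
    rate_hr = detected["grazing_rate_hr"].dropna().to_numpy()
    specific = detected["specific_grazing"].dropna().to_numpy()
    fg = constants.prey_carbon_fg
    hourly = _stats(rate_hr * fg * 1e-3)
    daily = _stats(np.array([
        convert_rate_to_daily_carbon(r, fg) for r in rate_hr]))
    clearance = _stats(specific * fg * 1e-3)
    if rate_hr.size:
        frac = (daily["mean"] / constants.pp_max,
                daily["mean"] / constants.pp_min)
    else:
        frac = None
    return CarbonBudget(
        group_key=group_key, n_detected=int(rate_hr.size),
        consumption_pg_c_ml_hr=hourly, consumption_ug_c_l_day=daily,
        clearance_pg_c_per_grazer=clearance, fraction_of_pp=frac)
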