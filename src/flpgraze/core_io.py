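"""Domain types, constants, and delimited-table I/O for FLP grazing experiments.

The unit of analysis is a single fluorescently-labeled-prey (FLP) uptake
experiment: a volume of diffuse vent fluid, plume water, or background
seawater amended with stained, heat-killed bacteria, subsampled over 0-40
minutes while the number of FLP visible inside each protistan grazer is
counted by epifluorescence microscopy.

Unit conventions, applied package-wide:

* concentrations are per mL; per-litre quantities appear only in final
  carbon outputs,
* times are minutes since FLP addition; the single min->hr conversion
  happens in the hourly uptake (60 x slope),
* prey carbon is femtograms per cell, protist carbon picograms per cell.

Prokaryote concentrations that could not be counted (mineral precipitation
obscured the filters) are carried as an explicit ``UNCOUNTABLE`` sentinel in
files and as ``None`` in memory -- never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd

__all__ = [
    "UNCOUNTABLE",
    "Constants",
    "DEFAULT_CONSTANTS",
    "UptakeTimepoint",
    "GrazingExperiment",
    "GrazingRates",
    "PreyConcentration",
    "SchemaError",
    "AmbiguityError",
    "effective_prey_conc",
    "convert_rate_to_daily_carbon",
    "read_experiments",
    "read_timepoints",
    "write_experiments",
    "write_timepoints",
    "load_mcr_dataset",
]

#: File token for a prokaryote concentration that could not be counted.
UNCOUNTABLE = "UNCOUNTABLE"


class SchemaError(ValueError):
    """A delimited table is missing a mandatory column."""


class AmbiguityError(ValueError):
    """Duplicate (experiment_id, replicate_id, time_min) rows."""


@dataclass(frozen=True)
class Constants:
    """Single source of truth for the pipeline's fixed parameters.

    Attributes
    ----------
    fallback_prok_conc
        Campaign-average prokaryote abundance (cells ml^-1) substituted when
        a sample's own prokaryote count was uncountable.
    prey_carbon_fg
        Carbon content assumed per prokaryotic prey cell (fg C cell^-1).
    allometry_a, allometry_b
        Coefficients of the protist biovolume->carbon power law
        pg C cell^-1 = a * biovolume^b (biovolume in um^3), for mixed
        protist assemblages excluding diatoms.
    pp_min, pp_max
        Literature bounds on chemosynthetic primary production at diffuse
        vents (ug C L^-1 day^-1); the denominator of the budget's
        fraction-of-production figure.
    flp_fraction_range
        Target FLP dose for shipboard experiments, as a fraction of the
        in-situ prokaryote community.
    igt_flp_conc
        FLP dose used in isobaric gas-tight (IGT) incubations (cells ml^-1).
    """

    fallback_prok_conc: float = 7.11e4
    prey_carbon_fg: float = 86.0
    allometry_a: float = 0.216
    allometry_b: float = 0.939
    pp_min: float = 17.3
    pp_max: float = 321.4
    flp_fraction_range: tuple[float, float] = (0.20, 0.25)
    igt_flp_conc: float = 1e4

    def __post_init__(self) -> None:
        for name in ("fallback_prok_conc", "prey_carbon_fg", "allometry_a",
                     "allometry_b", "pp_min", "pp_max", "igt_flp_conc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.flp_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("flp_fraction_range must satisfy 0 < lo <= hi < 1")


DEFAULT_CONSTANTS = Constants()


@dataclass(frozen=True)
class UptakeTimepoint:
    """One microscopy count of ingested FLP at one time in one replicate."""

    time_min: float
    replicate_id: str
    n_grazers_counted: int
    total_flp_ingested: int
    is_final: bool = False

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")
        if self.n_grazers_counted < 0 or self.total_flp_ingested < 0:
            raise ValueError("counts must be >= 0")

    @property
    def mean_flp_per_grazer(self) -> float:
        """Mean ingested FLP per grazer; undefined when no grazers counted."""
        if self.n_grazers_counted == 0:
            raise ZeroDivisionError(
                "mean FLP per grazer undefined with zero grazers counted")
        return self.total_flp_ingested / self.n_grazers_counted


@dataclass
class GrazingExperiment:
    """Metadata, abundances, and uptake time series of one grazing assay.

    ``prok_cells_ml is None`` encodes the UNCOUNTABLE sentinel; use
    :func:`effective_prey_conc` to resolve the prey concentration actually
    used downstream.
    """

    experiment_id: str
    vent_field: str                      # "VonDamm" | "Piccard"
    site: str
    habitat: str                         # "vent" | "plume" | "background"
    approach: str                        # "ambient" | "igt"
    temperature_c: float
    euk_cells_ml: float
    prok_cells_ml: float | None = None
    prok_minmax: tuple[float, float] | None = None
    euk_minmax: tuple[float, float] | None = None
    flp_conc_t0: float | None = None
    timepoints: list[UptakeTimepoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vent_field not in ("VonDamm", "Piccard"):
            raise ValueError(f"unknown vent_field {self.vent_field!r}")
        if self.habitat not in ("vent", "plume", "background"):
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.approach not in ("ambient", "igt"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.euk_cells_ml < 0:
            raise ValueError("eukaryote concentration must be >= 0")
        if self.prok_cells_ml is not None and self.prok_cells_ml < 0:
            raise ValueError("prokaryote concentration must be >= 0")
        if self.timepoints:
            if self.flp_conc_t0 is None or self.flp_conc_t0 <= 0:
                raise ValueError(
                    "flp_conc_t0 must be positive when timepoints are present")
            times = sorted({tp.time_min for tp in self.timepoints})
            if times[0] != 0:
                raise ValueError("first timepoint must be at 0 min")
            per_rep: dict[str, list[float]] = {}
            for tp in sorted(self.timepoints,
                             key=lambda t: (t.time_min, t.replicate_id)):
                per_rep.setdefault(tp.replicate_id, []).append(tp.time_min)
            for rep, ts in per_rep.items():
                if any(b <= a for a, b in zip(ts, ts[1:])):
                    raise ValueError(
                        f"times not strictly increasing in replicate {rep!r}")
            self.timepoints = sorted(
                self.timepoints, key=lambda t: (t.time_min, t.replicate_id))


class PreyConcentration(NamedTuple):
    """Resolved prey concentration plus provenance of the value."""

    value: float
    source: str  # "counted" | "fallback"


def effective_prey_conc(exp: GrazingExperiment,
                        constants: Constants = DEFAULT_CONSTANTS,
                        ) -> PreyConcentration:
    """Prey (prokaryote) concentration to use downstream for ``exp``.

    Returns the sample's own count when available, otherwise the
    campaign-average fallback, recording which branch was taken.
    """
    if exp.prok_cells_ml is None:
        return PreyConcentration(constants.fallback_prok_conc, "fallback")
    return PreyConcentration(exp.prok_cells_ml, "counted")


@dataclass(frozen=True)
class GrazingRates:
    """The derived rate chain for one experiment.

    When the fitted uptake slope is non-positive the assay is below
    detection: ``below_detection`` is set and every rate (including the
    hourly uptake) is reported as zero, while ``slope_flp_per_grazer_min``
    retains the raw fitted value for diagnostics.
    """

    slope_flp_per_grazer_min: float
    hourly_uptake: float                 # FLP grazer^-1 hr^-1
    clearance_ml_per_grazer_hr: float
    specific_grazing: float              # prokaryotes grazer^-1 hr^-1
    grazing_rate_hr: float               # cells consumed ml^-1 hr^-1
    grazing_rate_day: float              # cells consumed ml^-1 day^-1
    turnover_pct_day: float              # % of prey standing stock day^-1
    below_detection: bool
    slope_stderr: float = math.nan
    prey_conc_source: str = "counted"

    def __post_init__(self) -> None:
        for name in ("hourly_uptake", "clearance_ml_per_grazer_hr",
                     "specific_grazing", "grazing_rate_hr",
                     "grazing_rate_day", "turnover_pct_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 after detection gating")


def convert_rate_to_daily_carbon(rate_hr: float,
                                 prey_carbon_fg: float =
                                 DEFAULT_CONSTANTS.prey_carbon_fg) -> float:
    """Convert a grazing rate to daily prey-carbon consumption.

    Parameters
    ----------
    rate_hr
        Grazing rate in prey cells consumed ml^-1 hr^-1.
    prey_carbon_fg
        Carbon per prey cell, fg C.

    Returns
    -------
    float
        ug C L^-1 day^-1.  (1 fg ml^-1 == 1e-6 ug L^-1.)
    """
    if rate_hr < 0:
        raise ValueError("grazing rate must be >= 0")
    return rate_hr * prey_carbon_fg * 24 * 1e-6


# ---------------------------------------------------------------------------
# Delimited-table I/O

_EXPERIMENT_COLUMNS = [
    "experiment_id", "vent_field", "site", "habitat", "approach",
    "temperature_C", "prok_cells_ml", "prok_min", "prok_max",
    "euk_cells_ml", "euk_min", "euk_max", "flp_conc_t0",
]
_TIMEPOINT_COLUMNS = [
    "experiment_id", "replicate_id", "time_min",
    "n_grazers_counted", "total_flp_ingested", "is_final",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _parse_prok(value) -> float | None:
    if isinstance(value, str) and value.strip().upper() == UNCOUNTABLE:
        return None
    return _opt_float(value)


def _minmax(lo, hi) -> tuple[float, float] | None:
    lo, hi = _opt_float(lo), _opt_float(hi)
    if lo is None or hi is None:
        return None
    return (lo, hi)


def read_timepoints(path: str | Path) -> dict[str, list[UptakeTimepoint]]:
    """Read ``timepoints.csv``; returns timepoints keyed by experiment_id."""
    df = pd.read_csv(path)
    _require_columns(df, _TIMEPOINT_COLUMNS, path)
    dup = df.duplicated(subset=["experiment_id", "replicate_id", "time_min"])
    if dup.any():
        rows = df.loc[dup, ["experiment_id", "replicate_id", "time_min"]]
        raise AmbiguityError(
            f"{path}: duplicate (experiment_id, replicate_id, time_min) "
            f"rows: {rows.to_dict('records')}")
    out: dict[str, list[UptakeTimepoint]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.experiment_id), []).append(UptakeTimepoint(
            time_min=float(row.time_min),
            replicate_id=str(row.replicate_id),
            n_grazers_counted=int(row.n_grazers_counted),
            total_flp_ingested=int(row.total_flp_ingested),
            is_final=str(row.is_final).strip().lower() in ("true", "1", "yes"),
        ))
    return out


def read_experiments(path: str | Path,
                     timepoints_path: str | Path | None = None,
                     ) -> list[GrazingExperiment]:
    """Read ``experiments.csv`` (optionally attaching ``timepoints.csv``).

    Unknown extra columns are ignored; a missing mandatory column raises
    :class:`SchemaError` naming it.  The prokaryote column accepts numbers
    or the :data:`UNCOUNTABLE` token.
    """
    df = pd.read_csv(path, dtype={"prok_cells_ml": str})
    _require_columns(df, _EXPERIMENT_COLUMNS, path)
    tps = read_timepoints(timepoints_path) if timepoints_path else {}
    experiments = []
    for row in df.itertuples(index=False):
        eid = str(row.experiment_id)
        experiments.append(GrazingExperiment(
            experiment_id=eid,
            vent_field=str(row.vent_field),
            site=str(row.site),
            habitat=str(row.habitat),
            approach=str(row.approach),
            temperature_c=float(row.temperature_C),
            euk_cells_ml=float(row.euk_cells_ml),
            prok_cells_ml=_parse_prok(row.prok_cells_ml),
            prok_minmax=_minmax(row.prok_min, row.prok_max),
            euk_minmax=_minmax(row.euk_min, row.euk_max),
            flp_conc_t0=_opt_float(row.flp_conc_t0),
            timepoints=tps.get(eid, []),
        ))
    return experiments


def write_experiments(path: str | Path,
                      experiments: Sequence[GrazingExperiment]) -> None:
    """Write experiments back out in the documented schema (round-trips)."""
    rows = []
    for e in experiments:
        rows.append({
            "experiment_id": e.experiment_id,
            "vent_field": e.vent_field,
            "site": e.site,
            "habitat": e.habitat,
            "approach": e.approach,
            "temperature_C": e.temperature_c,
            "prok_cells_ml": (UNCOUNTABLE if e.prok_cells_ml is None
                              else repr(e.prok_cells_ml)),
            "prok_min": e.prok_minmax[0] if e.prok_minmax else None,
            "prok_max": e.prok_minmax[1] if e.prok_minmax else None,
            "euk_cells_ml": repr(e.euk_cells_ml),
            "euk_min": e.euk_minmax[0] if e.euk_minmax else None,
            "euk_max": e.euk_minmax[1] if e.euk_minmax else None,
            "flp_conc_t0": (None if e.flp_conc_t0 is None
                            else repr(e.flp_conc_t0)),
        })
    pd.DataFrame(rows, columns=_EXPERIMENT_COLUMNS).to_csv(path, index=False)


def write_timepoints(path: str | Path,
                     experiments: Sequence[GrazingExperiment]) -> None:
    rows = []
    for e in experiments:
        for tp in e.timepoints:
            rows.append({
                "experiment_id": e.experiment_id,
                "replicate_id": tp.replicate_id,
                "time_min": tp.time_min,
                "n_grazers_counted": tp.n_grazers_counted,
                "total_flp_ingested": tp.total_flp_ingested,
                "is_final": tp.is_final,
            })
    pd.DataFrame(rows, columns=_TIMEPOINT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged Mid-Cayman Rise dataset

def _mcr_path() -> Path:
    return Path(resources.files("flpgraze.data") / "mcr_grazing_experiments.csv")


def load_mcr_dataset(constants: Constants = DEFAULT_CONSTANTS,
                     ) -> tuple[list[GrazingExperiment], pd.DataFrame]:
    """Load the packaged Mid-Cayman Rise grazing-experiment table.

    Fourteen experiments (9 shipboard-ambient, 5 IGT) from the Von Damm and
    Piccard vent fields, transcribed digit-for-digit from the published
    campaign table, including its min/max abundance columns and the derived
    rate columns used by the reproduction audit.

    Returns
    -------
    (experiments, reference)
        ``experiments`` is a list of :class:`GrazingExperiment`;
        ``reference`` is a DataFrame carrying the published derived rate
        columns (``*_printed``) and the per-row ``status``
        (``detected`` / ``bd`` below-detection / ``na`` not countable).

    Notes
    -----
    Per-experiment FLP doses were not published.  For detected rows the
    loader back-derives ``flp_conc_t0`` as printed hourly uptake divided by
    printed clearance (the value implied by the published chain); for other
    rows it applies the 22.5%-of-prey dosing midpoint.  These FLP values are
    placeholders, not authoritative measurements.
    """
    path = _mcr_path()
    ref = pd.read_csv(path, dtype={"prok_cells_ml": str})
    experiments = []
    for row in ref.itertuples(index=False):
        prok = _parse_prok(row.prok_cells_ml)
        prok_eff = prok if prok is not None else constants.fallback_prok_conc
        hourly = _opt_float(row.hourly_uptake_printed)
        clearance = _opt_float(row.clearance_printed)
        if hourly is not None and clearance is not None and clearance > 0:
            flp = hourly / clearance
        else:
            flp = 0.225 * prok_eff
        experiments.append(GrazingExperiment(
            experiment_id=str(row.experiment_id),
            vent_field=str(row.vent_field),
            site=str(row.site),
            habitat=str(row.habitat),
            approach=str(row.approach),
            temperature_c=float(row.temperature_C),
            euk_cells_ml=float(row.euk_cells_ml),
            prok_cells_ml=prok,
            prok_minmax=_minmax(row.prok_min, row.prok_max),
            euk_minmax=_minmax(row.euk_min, row.euk_max),
            flp_conc_t0=flp,
        ))
    return experiments, ref
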