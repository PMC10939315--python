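"""Field-of-view epifluorescence counts -> cell concentrations.

Prey (bacteria and archaea) are concentrated on 0.2-um black polycarbonate
filters and counted DAPI-stained; grazers on 0.8-um filters.  A minimum of
30 fields of view (FOV) per sample at 100x magnification is standard
practice.  The count-to-concentration step scales the mean count per FOV by
the ratio of effective filtration area to FOV area and divides by the
volume filtered; the area ratio is a required input, not a hard-coded
microscope constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .core_io import UptakeTimepoint

__all__ = ["FovCountSet", "ConcentrationEstimate", "PooledMean",
           "concentration_from_fov", "mean_flp_per_grazer"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FovCountSet:
    """Per-FOV cell counts for one filter, with the scaling geometry."""

    cells_per_fov: tuple[int, ...]
    filter_area_mm2: float
    fov_area_mm2: float
    volume_filtered_ml: float
    stain: str = "DAPI"  # "DAPI" (prey) | "FITC" (FLP)

    def __post_init__(self) -> None:
        if len(self.cells_per_fov) < 1:
            raise ValueError("at least one field of view is required")
        if any(c < 0 for c in self.cells_per_fov):
            raise ValueError("FOV counts must be >= 0")
        if self.filter_area_mm2 <= 0 or self.fov_area_mm2 <= 0:
            raise ValueError("areas must be positive")
        if self.volume_filtered_ml <= 0:
            raise ValueError("volume filtered must be positive")
        if self.stain not in ("DAPI", "FITC"):
            raise ValueError(f"unknown stain {self.stain!r}")

    @property
    def n_fov(self) -> int:
        return len(self.cells_per_fov)


class ConcentrationEstimate(NamedTuple):
    mean: float              # cells ml^-1
    sem: float | None        # cells ml^-1; None when n_fov < 2
    n_fov: int


def concentration_from_fov(fc: FovCountSet) -> ConcentrationEstimate:
    """Cell concentration (cells ml^-1) from per-FOV counts.

    mean = mean(counts) * (filter_area / fov_area) / volume; the SEM scales
    the per-FOV standard error of the mean by the same factor.  A single
    FOV yields an undefined SEM (``None``), logged as a warning.
    """
    counts = np.asarray(fc.cells_per_fov, dtype=float)
    factor = (fc.filter_area_mm2 / fc.fov_area_mm2) / fc.volume_filtered_ml
    mean = counts.mean() * factor
    if fc.n_fov < 2:
        logger.warning("SEM undefined with a single field of view")
        sem = None
    else:
        sem = counts.std(ddof=1) / math.sqrt(fc.n_fov) * factor
    if fc.n_fov < 30:
        logger.info("only %d fields of view counted (<30)", fc.n_fov)
    return ConcentrationEstimate(mean=mean, sem=sem, n_fov=fc.n_fov)


class PooledMean(NamedTuple):
    mean: float              # FLP grazer^-1
    sem: float | None        # across replicate means; None when <2 replicates
    n_grazers: int


def mean_flp_per_grazer(timepoints: Sequence[UptakeTimepoint]) -> PooledMean:
    """Pooled mean FLP per grazer across replicate counts at one time.

    The mean is count-weighted (total FLP over total grazers observed), not
    a mean of replicate means; the SEM, when >= 2 replicates carry grazers,
    is the standard error across replicate means.  All-zero grazer counts
    make the mean undefined and raise, so callers can exclude the timepoint
    from fitting.
    """
    if not timepoints:
        raise ValueError("no counts supplied")
    usable = [tp for tp in timepoints if tp.n_grazers_counted > 0]
    if not usable:
        raise ZeroDivisionError(
            "mean FLP per grazer undefined: zero grazers counted in every "
            "replicate")
    total_grazers = sum(tp.n_grazers_counted for tp in usable)
    pooled = sum(tp.total_flp_ingested for tp in usable) / total_grazers
    if len(usable) >= 2:
        rep_means = np.array([tp.mean_flp_per_grazer for tp in usable])
        sem = rep_means.std(ddof=1) / math.sqrt(len(usable))
    else:
        sem = None
    return PooledMean(mean=pooled, sem=sem, n_grazers=total_grazers)
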