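"""Synthetic FLP experiments, morphometry, and ASV tables.

Every analysis stage in this package can be exercised without the original
microscopy data by simulating inputs with the statistical structure the
estimators assume:

* ingestion is Poisson with a constant rate (no FLP depletion, no
  egestion), consistent with the linear-uptake model -- each counted
  grazer at time t carries Poisson(clearance x FLP x t / 60) tracer cells;
* the number of grazers found in the counted fields is itself Poisson;
* IGT incubations lose grazers at their final timepoint (bottle effects on
  cell abundance), modelled as thinning of the grazer count, not as a
  change in ingestion;
* ASV occupancy patterns are planted exactly by distribution class
  (vent-only / cosmopolitan / other), with negative-binomial counts inside
  occupied cells.

All randomness flows from one integer seed through a splittable
``numpy.random.SeedSequence``, so sub-simulations are individually
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import AsvTable
from .carbon import CellMorphometry
from .core_io import (Constants, DEFAULT_CONSTANTS, GrazingExperiment,
                      UptakeTimepoint)

__all__ = ["SimConfig", "SimTruth", "simulate_experiment",
           "simulate_morphometry", "simulate_asv_table"]


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated FLP uptake experiment.

    Defaults mirror the field campaign: a 20-25% FLP dose (midpoint 0.225)
    of the prey community for shipboard runs or a fixed 1e4 FLP ml^-1 for
    IGT runs, timepoints at 0/10/15/40 min, and on the order of 100
    grazers counted per timepoint.
    """

    true_clearance: float                  # mL grazer^-1 hr^-1
    grazer_conc: float = 370.0             # cells ml^-1
    prey_conc: float = 7.11e4              # cells ml^-1
    flp_mode: str = "fraction_of_prey"     # or "fixed"
    flp_fraction: float = 0.225
    flp_fixed: float = 1e4
    timepoints_min: tuple[float, ...] = (0.0, 10.0, 15.0, 40.0)
    n_replicates: int = 2
    grazers_counted_per_timepoint: float = 100.0
    approach: str = "ambient"              # "ambient" | "igt"
    igt_tf_dropout: float = 0.0            # grazer loss fraction at IGT Tf
    vent_field: str = "VonDamm"
    habitat: str = "vent"
    site: str = "synthetic"
    temperature_c: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_clearance < 0:
            raise ValueError("true_clearance must be >= 0")
        if self.flp_mode not in ("fraction_of_prey", "fixed"):
            raise ValueError(f"unknown flp_mode {self.flp_mode!r}")
        if self.flp_mode == "fraction_of_prey" and not (
                0.20 <= self.flp_fraction <= 0.25):
            raise ValueError("flp_fraction must lie in [0.20, 0.25]")
        if not (0.0 <= self.igt_tf_dropout < 1.0):
            raise ValueError("igt_tf_dropout must lie in [0, 1)")
        if min(self.timepoints_min) != 0:
            raise ValueError("timepoints must start at 0 min")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def flp_conc(self) -> float:
        if self.flp_mode == "fixed":
            return self.flp_fixed
        return self.flp_fraction * self.prey_conc

    @property
    def expected_slope(self) -> float:
        """Expected uptake slope, FLP grazer^-1 min^-1."""
        return self.true_clearance * self.flp_conc / 60.0


@dataclass(frozen=True)
class SimTruth:
    """Hidden generating parameters for recovery tests."""

    experiment_id: str
    true_clearance: float
    flp_conc: float
    expected_slope: float


def simulate_experiment(cfg: SimConfig,
                        experiment_id: str = "sim",
                        ) -> tuple[GrazingExperiment, SimTruth]:
    """Draw one synthetic uptake experiment plus its truth record.

    At each timepoint and replicate the number of grazers counted is
    Poisson(expected count); the total ingested FLP across them is
    Poisson(n x clearance x FLP x t / 60).  At the final timepoint of an
    IGT run the expected grazer count is thinned by ``igt_tf_dropout``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    flp = cfg.flp_conc
    t_final = max(cfg.timepoints_min)
    timepoints: list[UptakeTimepoint] = []
    for t in sorted(cfg.timepoints_min):
        is_final = t == t_final
        expected_n = cfg.grazers_counted_per_timepoint
        if is_final and cfg.approach == "igt":
            expected_n *= 1.0 - cfg.igt_tf_dropout
        lam = cfg.true_clearance * flp * t / 60.0
        for rep in range(cfg.n_replicates):
            n = int(rng.poisson(expected_n))
            total = int(rng.poisson(n * lam)) if n > 0 and lam > 0 else 0
            timepoints.append(UptakeTimepoint(
                time_min=float(t), replicate_id=f"r{rep + 1}",
                n_grazers_counted=n, total_flp_ingested=total,
                is_final=is_final))
    exp = GrazingExperiment(
        experiment_id=experiment_id, vent_field=cfg.vent_field,
        site=cfg.site, habitat=cfg.habitat, approach=cfg.approach,
        temperature_c=cfg.temperature_c, euk_cells_ml=cfg.grazer_conc,
        prok_cells_ml=cfg.prey_conc, flp_conc_t0=flp,
        timepoints=timepoints)
    truth = SimTruth(experiment_id=experiment_id,
                     true_clearance=cfg.true_clearance, flp_conc=flp,
                     expected_slope=cfg.expected_slope)
    return exp, truth


def simulate_morphometry(n_cells: int, log_mean_h: float = math.log(12.0),
                         log_sd: float = 0.6, aspect: float = 0.6,
                         habitat: str = "vent", seed: int = 0,
                         ) -> list[CellMorphometry]:
    """Lognormal cell sizes: h ~ LogNormal(log_mean_h, log_sd), d = aspect*h.

    ``aspect`` in (0, 1]: 1 gives spheres.  Deterministic under a fixed
    seed; n_cells = 0 returns an empty list.
    """
    if not (0 < aspect <= 1):
        raise ValueError("aspect ratio must lie in (0, 1]")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    h = np.exp(rng.normal(log_mean_h, log_sd, size=n_cells))
    return [CellMorphometry(cell_id=f"cell{i + 1}", h_um=float(hi),
                            d_um=float(aspect * hi), habitat=habitat)
            for i, hi in enumerate(h)]


def _occupancy_masks(rng: np.random.Generator, klass: str,
                     n_per_habitat: int) -> dict[str, np.ndarray]:
    """Sample-occupancy masks per habitat for one ASV of a planted class."""
    def some(minimum: int = 1) -> np.ndarray:
        k = int(rng.integers(minimum, n_per_habitat + 1))
        mask = np.zeros(n_per_habitat, dtype=bool)
        mask[rng.choice(n_per_habitat, size=k, replace=False)] = True
        return mask

    none = np.zeros(n_per_habitat, dtype=bool)
    if klass == "vent_only":
        return {"vent": some(), "plume": none, "background": none}
    if klass == "cosmopolitan":
        return {"vent": some(), "plume": some(), "background": some()}
    # "other": any nonzero pattern that is neither vent-only nor
    # present in all three habitats
    patterns = [("plume",), ("background",), ("plume", "background"),
                ("vent", "plume"), ("vent", "background")]
    chosen = patterns[int(rng.integers(len(patterns)))]
    return {h: (some() if h in chosen else none.copy())
            for h in ("vent", "plume", "background")}


def simulate_asv_table(n_asvs: int = 100, n_samples_per_habitat: int = 3,
                       vent_only_fraction: float = 0.3,
                       cosmopolitan_fraction: float = 0.5,
                       nb_mean: float = 50.0, nb_dispersion: float = 1.0,
                       seed: int = 0) -> tuple[AsvTable, pd.Series]:
    """Build an ASV table with exactly planted distribution classes.

    Class counts are fixed by construction: round(fraction x n_asvs)
    vent-only and cosmopolitan ASVs, the remainder ``other``.  Counts in
    occupied cells are 1 + NegativeBinomial(nb_dispersion, p) with mean
    ``nb_mean``.  Returns the table and the planted class per ASV;
    ``classify_distribution`` recovers the planted classes exactly.
    """
    if vent_only_fraction < 0 or cosmopolitan_fraction < 0 or (
            vent_only_fraction + cosmopolitan_fraction > 1):
        raise ValueError("class fractions must be >= 0 and sum to <= 1")
    if n_asvs < 1 or n_samples_per_habitat < 1:
        raise ValueError("need at least one ASV and one sample per habitat")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_vent_only = round(vent_only_fraction * n_asvs)
    n_cosmo = round(cosmopolitan_fraction * n_asvs)
    planted = (["vent_only"] * n_vent_only + ["cosmopolitan"] * n_cosmo +
               ["other"] * (n_asvs - n_vent_only - n_cosmo))

    habitats = ("vent", "plume", "background")
    sample_ids = [f"{h}{i + 1}" for h in habitats
                  for i in range(n_samples_per_habitat)]
    counts = pd.DataFrame(
        0, index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index([f"asv{i + 1}" for i in range(n_asvs)],
                         name="asv_id"))
    # NB with mean nb_mean: p = r / (r + mean)
    p = nb_dispersion / (nb_dispersion + nb_mean)
    for asv, klass in zip(counts.columns, planted):
        masks = _occupancy_masks(rng, klass, n_samples_per_habitat)
        for h in habitats:
            idx = [f"{h}{i + 1}" for i in range(n_samples_per_habitat)]
            occupied = masks[h]
            if occupied.any():
                draws = 1 + rng.negative_binomial(
                    nb_dispersion, p, size=int(occupied.sum()))
                counts.loc[np.array(idx)[occupied], asv] = draws

    divisions = ("Ciliophora", "Dinoflagellata", "Stramenopiles",
                 "Hacrobia", "Rhizaria")
    taxonomy = pd.DataFrame({
        "division": rng.choice(divisions, size=n_asvs),
        "family": [f"family{int(rng.integers(1, 11))}" for _ in range(n_asvs)],
    }, index=counts.columns)
    meta = pd.DataFrame({
        "habitat": [h for h in habitats
                    for _ in range(n_samples_per_habitat)],
        "role": "in_situ",
        "site": "synthetic",
        "vent_field": "VonDamm",
    }, index=counts.index)
    table = AsvTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)
    return table, pd.Series(planted, index=counts.columns, name="planted")
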