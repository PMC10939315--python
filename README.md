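# flpgraze

Protistan grazing rates, cell biomass, and a carbon-flux budget for
deep-sea hydrothermal vent microbial food webs, from
fluorescently-labeled-prey (FLP) uptake experiments and epifluorescence
microscopy counts.

Diffuse hydrothermal fluids host dense communities of bacteria, archaea,
and the microbial eukaryotes (protists) that graze on them.  Grazing is
the main route by which chemosynthetic primary production moves up the
vent food web, but measuring it is hard: counts arrive as ingested-tracer
tallies per cell per timepoint, and the path from those tallies to
"percent of the prey community consumed per day" crosses half a dozen
unit conversions and exclusion rules.  `flpgraze` packages that pipeline
for ecologists working with FLP assays — at vents or anywhere else the
linear-uptake estimator applies.

## The model

A grazer clearing water at rate *C* (mL grazer⁻¹ hr⁻¹) in water spiked
with *F* FLP ml⁻¹ accumulates visible tracer linearly; OLS on pooled
mean FLP per grazer vs time (minutes) gives slope *m*, and then

    hourly uptake = 60·m                    FLP grazer⁻¹ hr⁻¹
    C  = hourly uptake / F                  mL grazer⁻¹ hr⁻¹
    SG = C × prokaryotes ml⁻¹               prey grazer⁻¹ hr⁻¹
    G  = SG × eukaryotes ml⁻¹               cells consumed ml⁻¹ hr⁻¹
    turnover = 100 × 24·G / prokaryotes ml⁻¹   % day⁻¹

Assays with slope ≤ 0 are below detection: reported as zero, excluded
from group means.  IGT (isobaric gas-tight, in-situ pressure)
experiments drop their final timepoint before fitting.  Biomass uses
prolate-spheroid biovolume V = (π/6)·d²·h and the diatom-free allometry
pg C cell⁻¹ = 0.216·V^0.939; the consumption budget prices prey at
86 fg C cell⁻¹ and compares against chemosynthetic primary production
(17.3–321.4 μg C L⁻¹ day⁻¹).  Details, conventions, and edge cases:
[docs/methods.md](docs/methods.md).

The package ships the Mid-Cayman Rise campaign table (14 experiments at
the Von Damm and Piccard vent fields) as a packaged dataset, a
reproduction audit for the published derived values, ASV-table utilities
for the paired 18S amplicon survey, and a seeded synthetic-experiment
generator so every stage is testable without the original microscopy
data.

## Worked example

Simulate one vent assay at a known clearance rate and recover it:

```python
from flpgraze import SimConfig, simulate_experiment, fit_uptake_slope, rate_chain

cfg = SimConfig(true_clearance=3.7e-5, prey_conc=4811 / 0.225, seed=11)
exp, truth = simulate_experiment(cfg, "demo")
fit = fit_uptake_slope(exp)
r = rate_chain(fit, exp)
print(f"fitted slope   : {fit.slope:.5f} +/- {fit.stderr:.5f} FLP/grazer/min")
print(f"clearance      : {r.clearance_ml_per_grazer_hr:.3e} mL/grazer/hr")
print(f"specific graze : {r.specific_grazing:.3f} prey/grazer/hr")
print(f"grazing rate   : {r.grazing_rate_hr:.1f} cells/ml/hr")
print(f"turnover       : {r.turnover_pct_day:.2f} %/day")
```

```
fitted slope   : 0.00326 +/- 0.00059 FLP/grazer/min
clearance      : 4.062e-05 mL/grazer/hr
specific graze : 0.869 prey/grazer/hr
grazing rate   : 321.3 cells/ml/hr
turnover       : 36.07 %/day
```

The generating clearance was 3.70 × 10⁻⁵ mL grazer⁻¹ hr⁻¹; a single
assay recovers it within its ~30% per-run uncertainty (the slope's 95%
interval uses the t quantile at 2 degrees of freedom), and the chain
says this simulated grazer population would remove about a third of the
standing prey stock per day.

The same chain runs from files on the command line:

```sh
flpgraze simulate --seed 42 --out-dir fixtures/
flpgraze rates --experiments fixtures/experiments.csv \
               --timepoints fixtures/timepoints.csv --out rates.csv
flpgraze summarize --rates rates.csv --by habitat --out summary.csv
flpgraze budget --rates rates.csv --out budget.csv
```

Recompute the published campaign tables and their audit:

```sh
flpgraze reproduce --out-dir repro/
# audit: {'PASS': 63, 'EXPECTED_MISMATCH': 41, 'OUT_OF_SCOPE': 1}
```

`repro/audit.csv` lists every published derived cell with its
recomputation, relative error, and status.  All 63 recomputable cells
pass at their documented tolerances — e.g. the detected-assay vent-group
grazing mean recomputes to 6.92 × 10³ cells consumed ml⁻¹ hr⁻¹ against
the reported 6.9 × 10³, and IGT vent carbon consumption to 980 pg C
ml⁻¹ hr⁻¹.  Cells that are knowably not derivable from the printed
inputs (group carbon factors built from unpublished per-cell data, and
four consumption cells whose printed values match the other member of
their row pair) are flagged `EXPECTED_MISMATCH` with the reason, never
silently matched.

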