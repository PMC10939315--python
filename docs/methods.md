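# Methods

## The estimation problem

Protistan grazing pressure in a water sample is measured by spiking the
sample with fluorescently labeled prey (FLP) — heat-killed, DTAF-stained
bacteria — and counting, by epifluorescence microscopy at a series of
timepoints, how many FLP are visible inside each protistan cell.  If
grazers clear water at a constant rate and FLP are a passive tracer, the
mean number of FLP per grazer grows linearly in time, and the whole
trophic calculation hangs off that one slope.

`flpgraze` implements the chain as used for the Mid-Cayman Rise campaign
(Von Damm and Piccard vent fields; diffuse vent fluid, plume, and
background seawater; shipboard-ambient and isobaric gas-tight (IGT)
incubations):

| quantity | units | definition |
|---|---|---|
| slope *m* | FLP grazer⁻¹ min⁻¹ | OLS fit of pooled mean FLP per grazer vs time |
| hourly uptake | FLP grazer⁻¹ hr⁻¹ | 60·*m* |
| clearance rate | mL grazer⁻¹ hr⁻¹ | hourly uptake / FLP ml⁻¹ at T0 |
| specific grazing | prey grazer⁻¹ hr⁻¹ | clearance × prokaryotes ml⁻¹ |
| grazing rate | cells ml⁻¹ hr⁻¹ | specific × eukaryotes ml⁻¹ |
| daily grazing | cells ml⁻¹ day⁻¹ | 24 × grazing rate |
| turnover | % day⁻¹ | 100 × daily grazing / prokaryotes ml⁻¹ |

Times are carried in minutes everywhere; the single minutes→hours
conversion happens in the hourly uptake, so no rate can be double-scaled.
Concentrations are per mL; only final carbon outputs are per litre.

### Fitting and exclusion rules

* The fit is unweighted OLS on the *pooled* per-timepoint means (total
  FLP over total grazers observed across replicates).  A count-weighted
  option is deliberately not the default: the published rates derive from
  the pooled-mean convention.  Replicate-level SEM is reported separately
  and never mixed into the OLS slope standard error.
* IGT experiments drop their final (Tf) timepoint before fitting.
  Grazer abundance collapses at Tf in pressurized chambers (bottle
  effects), which would otherwise corrupt the slope.  Ambient
  experiments keep all timepoints.
* A fitted slope ≤ 0 means grazing was **below detection**: the assay is
  flagged, all rates are reported as zero, and flagged assays are
  excluded from group means while remaining in exports as zeros.  The
  gate includes exactly-flat series (slope = 0) because a flat series
  carries no evidence of grazing.
* Timepoints at which no replicate counted a grazer are dropped with a
  warning, never imputed.

### Prey concentration fallback

Four experiments had uncountable prokaryote concentrations (mineral
precipitation on the filters).  Files carry the literal token
`UNCOUNTABLE` (in memory `None`) — never zero, which would silently
poison the specific-grazing and turnover denominators.  Downstream
calculations substitute the campaign-average 7.11 × 10⁴ cells ml⁻¹, and
every rate records which branch was taken.

### Group summaries

Group statistics (habitat, vent field, experimental approach) are
per-experiment-row: repeated samplings of one physical fluid (e.g. the
three Shrimpocalypse rows) each count once.  This is the only convention
that reproduces the published vent prokaryote mean of 1.4 × 10⁵ cells
ml⁻¹.  Means are over detected assays only; a group with no detected
assay reports NaN, not zero.

## Microscopy counts

Cell concentration from field-of-view (FOV) counts is mean cells per FOV
× (effective filter area / FOV area) / volume filtered, with the SEM
scaled identically.  The area ratio is a required input, not a hard-coded
microscope constant, because it depends on the rig.  Field practice for
this dataset was ≥ 30 FOV per sample at 100×; fewer triggers an
informational log, a single FOV makes the SEM undefined.

## Biomass and the carbon budget

Cells are prolate spheroids: biovolume V = (π/6)·d²·h with h the longest
dimension and d its cross section (μm).  Carbon per cell follows the
mixed-assemblage, diatom-free allometry pg C = 0.216·V^0.939.  Because
the exponent is below 1 the law is concave, so the package exposes both
population conventions and keeps them distinct:

* `per_cell` (default): convert each cell, then average — matches how
  the published group factors (109.2 pg C cell⁻¹ non-vent, 400.8 vent)
  were built;
* `mean_volume`: convert the mean biovolume — always ≥ the per-cell
  average, a relationship asserted in the tests to guard against
  silently swapping conventions.

Population biomass is pg C cell⁻¹ × cells ml⁻¹ × 10⁻³ μg C L⁻¹.  Group
brackets apply the group's single carbon factor to the group's mean/min/
max abundances — the convention that reproduces the published non-vent
bracket (17.2 / 8.7 μg C L⁻¹).

The consumption budget prices each consumed prokaryote at 86 fg C:
hourly consumption is the grazing rate × 86 × 10⁻³ pg C ml⁻¹ hr⁻¹; daily
consumption converts each assay to μg C L⁻¹ day⁻¹ before aggregating.
The fraction of chemosynthetic primary production is always reported as
a pair against the published production bounds (17.3–321.4 μg C L⁻¹
day⁻¹), never collapsed to one number, because production is only known
as a range.

## ASV-table operations

The amplicon side works on a samples × ASVs integer count matrix with
PR2-style taxonomy and per-sample metadata.  Habitat-distribution
classes: *vent-only* (nonzero only in vent samples), *cosmopolitan*
(nonzero in vent AND plume AND background), everything else *other*;
zero-total ASVs have no class.  Presence means count ≥ 1 — no
relative-abundance floor.  The captured community of an incubation is
the set of ASVs present in both the final-timepoint sample and its
paired in-situ sample.  The centered log-ratio transform is
log(x + pseudocount) centered per sample; the pseudocount defaults to 1
(integer counts) and is exposed as a parameter.  Enrichment of a
taxonomic group during an incubation uses raw totals: enriched iff
sequences and/or distinct ASVs increased from in-situ to Tf.  The
beta-binomial differential-abundance model (corncob) is not
reimplemented; the enrichment table reserves a `corncob_coefficient`
column for externally fitted results.

## Synthetic experiments

The generator draws what the estimators assume:

* ingestion is Poisson with constant rate — each counted grazer at time
  t carries Poisson(clearance × FLP × t/60) tracer cells.  No FLP
  depletion (control counts in the field data were stable) and no
  egestion; consequently the whole chain is exactly linear in the true
  clearance, which the end-to-end tests exploit;
* grazers found in the counted fields are Poisson around the expected
  count (default 100 per timepoint);
* default conditions mirror the campaign: FLP dose 22.5% of the prey
  community (shipboard; the protocol range was 20–25%) or a fixed 10⁴
  ml⁻¹ (IGT), timepoints 0/10/15/40 min, duplicate incubations;
* the IGT Tf anomaly is modelled as grazer loss (thinning of the Tf
  count), not an ingestion change, matching its attribution to bottle
  effects on cell abundance;
* ASV tables plant occupancy classes exactly by construction, with
  1 + negative-binomial counts in occupied cells;
* all randomness flows from one seed through a splittable
  `SeedSequence`, so identical configurations are bit-identical and
  sub-simulations re-run independently.

What the generator does **not** emulate: functional-response saturation,
FLP selectivity or avoidance, cell lysis during handling, tag fading,
taxon-specific count biases, or any geochemistry.  Passing recovery
tests therefore show the estimator is consistent for the model it
assumes — not that real vent assays are free of those effects.

At the campaign's own conditions (clearance 3.7 × 10⁻⁵ mL grazer⁻¹
hr⁻¹, FLP ≈ 4.8 × 10³ ml⁻¹, ~100 grazers per timepoint, 0/10/15/40 min)
the per-run slope uncertainty is ~30% relative, so the 200-run recovery
test constrains the mean estimate to a few percent.  Confidence
intervals for the slope use the t quantile at n − 2 degrees of freedom;
with four timepoints that multiplier is 4.30, not 2 — a ±2·SE band has
at most ~82% coverage at these sample sizes even under ideal noise, and
empirically less, because Poisson noise grows with time and OLS assumes
it does not.  At zero true clearance every ingestion count is exactly
zero, the fitted series is flat, and the below-detection gate fires in
100% of runs.

## Reproduction audit

`flpgraze reproduce` (and `flpgraze.reproduce.reproduce_tables`)
recomputes every derivable published cell from the packaged campaign
table and grades each against print.  A recomputed value *agrees* when
its relative error is within the section tolerance or it rounds to the
printed figure at the printed precision.  Tolerances: 2.5% for
rate-chain cells (set by the 3-significant-figure printed clearance;
the worst printed case is the 2.40 × 10⁻⁴ clearance row at ~1.6%), 1%
for group means of printed columns and biomass brackets, and 2.5% for
consumption means (the two-decimal printed specific-grazing column
propagates up to ~2.3% into small group means).

Cells knowably not recomputable from the packaged inputs are marked
`EXPECTED_MISMATCH` with a reason, never silently passed: the vent
biomass rows (published values used unpublished per-experiment carbon
factors), the reported group-average eukaryote abundances, the non-vent
mean clearance cell, and four consumption row-pairs whose printed values
each match the *other* member of the pair (an apparent transposition in
the published table — the audit's recomputations agree with the swapped
cells to ≤ 0.5%).  Published ASV tallies that require the deposited
sequence data are `OUT_OF_SCOPE`; those operations are validated on
synthetic tables with planted truth instead.

## Numerical notes and edge cases

* Slope fitting uses `scipy.stats.linregress`; an exactly flat series
  short-circuits to slope 0 with stderr 0 (the residual-based stderr is
  0/0 there).
* On a below-detection assay the raw fitted slope is retained for
  diagnostics while the hourly uptake and all downstream rates are
  zeroed; the exact identity hourly = 60·slope therefore holds on
  detected assays.
* Zero FLP dose with timepoints, zero prey with a positive slope, and
  negative inputs raise immediately rather than propagating NaN.
* CLR is implemented directly (log + row centering) and cross-checked in
  the tests against scikit-bio's implementation as an independent
  oracle.
* All CLI outputs are written atomically (write-then-rename) and inputs
  are never mutated; the resolved constant set is logged so runs can be
  regenerated bit-identically.

## Problem sizes

The test suite and acceptance script run the full packaged dataset (14
experiments), 200-run recovery and null-calibration ensembles, 1000
random instances for the OLS-vs-normal-equations equivalence, and
500-ASV synthetic tables — sizes at which every Monte-Carlo bound above
has comfortable margin while the whole suite stays in the seconds range.
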