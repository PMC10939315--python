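"""Recompute the campaign's derived tables and audit them against print.

The packaged Mid-Cayman Rise dataset carries the published inputs
(abundances, temperatures) and the published derived rate columns.  This
module re-runs the rate chain, group summaries, biomass brackets, and
carbon-consumption budgets from those inputs and compares every derivable
published value with its recomputation, at an explicit tolerance, in a
single audit report.

Comparison rule: a recomputed value agrees with a printed one when the
relative error is within the section tolerance OR the recomputation rounds
to the printed figure at its printed precision.  Tolerances (made explicit
because printed values are themselves rounded):

* rate-chain cells: 2.5% relative -- dominated by the 3-significant-figure
  rounding of the printed clearance column,
* group means of printed columns: 1%,
* consumption budgets: 2.5% -- the printed two-decimal specific-grazing
  column feeds these means,
* biomass brackets: 1%.

Published cells that are *known* not to be recomputable from the packaged
inputs are marked EXPECTED_MISMATCH (never silently passed), with a note
saying why: the vent biomass rows used unpublished per-experiment carbon
factors; the reported group-average eukaryote abundances do not follow
from the abundance table under any per-row convention; and four
consumption rows are each consistent with the printed values of the
*other* member of their row pair (an apparent transposition).  Published
ASV tallies that require the deposited sequence data are OUT_OF_SCOPE.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pandas as pd

from .carbon import population_biomass
from .core_io import Constants, DEFAULT_CONSTANTS, load_mcr_dataset
from .grazing import rates_from_clearance, summarize, summarize_abundance

__all__ = ["reference_frame", "reproduce_tables", "compare_printed",
           "NONVENT_CARBON_FACTOR_PG", "VENT_CARBON_FACTOR_PG"]

RATE_CHAIN_TOL = 0.025
GROUP_TOL = 0.01
CONSUMPTION_TOL = 0.025
BIOMASS_TOL = 0.01

#: Published population carbon factors (pg C cell^-1) derived from the
#: campaign's morphometry; inputs to the biomass bracket audit.
NONVENT_CARBON_FACTOR_PG = 109.2
VENT_CARBON_FACTOR_PG = 400.8

_PRINTED_RE = re.compile(r"^\s*(-?\d+(?:\.(\d+))?)(?:e(-?\d+))?\s*$")


def _parse_printed(printed: str) -> tuple[float, int, int]:
    """Parse a printed figure into (value, mantissa decimals, exponent)."""
    m = _PRINTED_RE.match(printed)
    if m is None:
        raise ValueError(f"unparseable printed value {printed!r}")
    mantissa = float(m.group(1))
    decimals = len(m.group(2)) if m.group(2) else 0
    exponent = int(m.group(3)) if m.group(3) else 0
    return mantissa * 10.0 ** exponent, decimals, exponent


def compare_printed(computed: float, printed: str, rel_tol: float,
                    ) -> tuple[float, float, bool]:
    """Compare a recomputed value against a printed figure.

    Returns (printed value, relative error, agrees).  Agreement means the
    relative error is within ``rel_tol`` or the computed value rounds to
    the printed figure at its printed precision (which also covers printed
    zeros).
    """
    value, decimals, exponent = _parse_printed(printed)
    if value == 0:
        rel_err = math.inf if computed != 0 else 0.0
    else:
        rel_err = abs(computed - value) / abs(value)
    mantissa = value / 10.0 ** exponent
    rounds = abs(round(computed / 10.0 ** exponent, decimals)
                 - mantissa) < 10.0 ** (-decimals - 6)
    return value, rel_err, (rel_err <= rel_tol) or rounds


def _audit_row(section: str, item: str, quantity: str, printed: str,
               computed: float, rel_tol: float, expected: str = "PASS",
               note: str = "") -> dict:
    value, rel_err, ok = compare_printed(computed, printed, rel_tol)
    if expected == "EXPECTED_MISMATCH":
        status = "EXPECTED_MISMATCH"
    else:
        status = "PASS" if ok else "FAIL"
    return {"section": section, "item": item, "quantity": quantity,
            "printed": value, "computed": computed, "rel_err": rel_err,
            "status": status, "note": note}


def reference_frame(constants: Constants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """The packaged dataset as one flat frame with parsed printed columns.

    One row per experiment; ``*_printed`` columns are floats (NaN where the
    table prints below-detection or not-countable), ``prok_eff`` resolves
    the uncountable sentinel to the campaign fallback, and
    ``below_detection`` mirrors the printed status.
    """
    experiments, ref = load_mcr_dataset(constants)
    rows = []
    for exp, raw in zip(experiments, ref.itertuples(index=False)):
        prok_counted = exp.prok_cells_ml
        rows.append({
            "experiment_id": exp.experiment_id,
            "vent_field": exp.vent_field, "site": exp.site,
            "habitat": exp.habitat, "approach": exp.approach,
            "status": raw.status,
            "euk_cells_ml": exp.euk_cells_ml,
            "prok_cells_ml": (np.nan if prok_counted is None
                              else prok_counted),
            "prok_eff": (constants.fallback_prok_conc
                         if prok_counted is None else prok_counted),
            "hourly_printed": _to_float(raw.hourly_uptake_printed),
            "grazing_printed": _to_float(raw.grazing_rate_printed),
            "clearance_printed": _to_float(raw.clearance_printed),
            "specific_printed": _to_float(raw.specific_grazing_printed),
            "turnover_printed": _to_float(raw.turnover_printed),
            "below_detection": raw.status == "bd",
        })
    return pd.DataFrame(rows)


def _to_float(v) -> float:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return np.nan
    return f


def _derived_rates(ref: pd.DataFrame,
                   constants: Constants) -> pd.DataFrame:
    """Full-precision rate chain recomputed from the printed clearance."""
    experiments, _ = load_mcr_dataset(constants)
    by_id = {e.experiment_id: e for e in experiments}
    rows = []
    for r in ref.itertuples(index=False):
        exp = by_id[r.experiment_id]
        row = {"experiment_id": r.experiment_id, "status": r.status,
               "habitat": r.habitat, "vent_field": r.vent_field,
               "approach": r.approach}
        if r.status == "detected":
            rates = rates_from_clearance(r.clearance_printed, exp, constants)
            row.update({
                "clearance_ml_per_grazer_hr": rates.clearance_ml_per_grazer_hr,
                "specific_grazing": rates.specific_grazing,
                "grazing_rate_hr": rates.grazing_rate_hr,
                "grazing_rate_day": rates.grazing_rate_day,
                "turnover_pct_day": rates.turnover_pct_day,
                "below_detection": False,
            })
        elif r.status == "bd":
            row.update({"clearance_ml_per_grazer_hr": 0.0,
                        "specific_grazing": 0.0, "grazing_rate_hr": 0.0,
                        "grazing_rate_day": 0.0, "turnover_pct_day": 0.0,
                        "below_detection": True})
        else:  # not countable
            row.update({"clearance_ml_per_grazer_hr": np.nan,
                        "specific_grazing": np.nan, "grazing_rate_hr": np.nan,
                        "grazing_rate_day": np.nan,
                        "turnover_pct_day": np.nan,
                        "below_detection": False})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Audit sections

def _audit_rate_chain(ref: pd.DataFrame, constants: Constants) -> list[dict]:
    """Each printed derived cell vs recomputation from the printed cell
    one step upstream in the chain."""
    rows = []
    fmt = {"specific": "{:.2f}", "grazing": "{:.2f}", "turnover": "{:.1f}"}
    for r in ref.itertuples(index=False):
        if r.status != "detected":
            continue
        specific = r.clearance_printed * r.prok_eff
        grazing = r.specific_printed * r.euk_cells_ml
        turnover = 100.0 * (24.0 * r.grazing_printed) / r.prok_eff
        note = ("prey via campaign-average fallback"
                if math.isnan(r.prok_cells_ml) else "")
        for qty, computed, printed in [
                ("specific_grazing", specific,
                 fmt["specific"].format(r.specific_printed)),
                ("grazing_rate_hr", grazing,
                 fmt["grazing"].format(r.grazing_printed)),
                ("turnover_pct_day", turnover,
                 fmt["turnover"].format(r.turnover_printed))]:
            rows.append(_audit_row("rate_chain", r.experiment_id, qty,
                                   printed, computed, RATE_CHAIN_TOL,
                                   note=note))
    return rows


_SWAP_NOTE = ("matches the printed value of the other member of its row "
              "pair (apparent transposition in the published table)")


def _audit_group_means(ref: pd.DataFrame) -> list[dict]:
    usable = ref[ref["status"] != "na"].copy()
    usable["grazing_rate_hr"] = usable["grazing_printed"]

    def det_mean(mask) -> float:
        sub = usable[mask & ~usable["below_detection"]]
        return float(sub["grazing_rate_hr"].mean())

    vent = usable["habitat"] == "vent"
    nonvent = ~vent
    rows = []
    sub = usable[vent & ~usable["below_detection"]]["grazing_rate_hr"]
    rows += [
        _audit_row("group_means", "vent", "grazing_rate_mean", "6.9e3",
                   float(sub.mean()), GROUP_TOL),
        _audit_row("group_means", "vent", "grazing_rate_min", "116.9",
                   float(sub.min()), GROUP_TOL),
        _audit_row("group_means", "vent", "grazing_rate_max", "1.7e4",
                   float(sub.max()), GROUP_TOL),
    ]
    sub = usable[nonvent & ~usable["below_detection"]]["grazing_rate_hr"]
    rows += [
        _audit_row("group_means", "nonvent", "grazing_rate_mean", "65",
                   float(sub.mean()), GROUP_TOL),
        _audit_row("group_means", "nonvent", "grazing_rate_min", "24",
                   float(sub.min()), GROUP_TOL),
        _audit_row("group_means", "nonvent", "grazing_rate_max", "127",
                   float(sub.max()), GROUP_TOL),
    ]
    rows += [
        _audit_row("group_means", "vondamm_vent", "grazing_rate_mean",
                   "4.6e3", det_mean(vent & (usable["vent_field"]
                                             == "VonDamm")), GROUP_TOL),
        _audit_row("group_means", "piccard_vent", "grazing_rate_mean",
                   "1.2e4", det_mean(vent & (usable["vent_field"]
                                             == "Piccard")), GROUP_TOL),
        _audit_row("group_means", "vondamm_vent_igt", "grazing_rate_mean",
                   "2.4e3", det_mean(vent & (usable["vent_field"] == "VonDamm")
                                     & (usable["approach"] == "igt")),
                   GROUP_TOL, expected="EXPECTED_MISMATCH",
                   note="reported IGT-only average does not follow from the "
                        "experiment table under any per-row convention"),
        _audit_row("group_means", "piccard_vent_igt", "grazing_rate_mean",
                   "1.1e4", det_mean(vent & (usable["vent_field"] == "Piccard")
                                     & (usable["approach"] == "igt")),
                   GROUP_TOL, expected="EXPECTED_MISMATCH",
                   note="reported IGT-only average does not follow from the "
                        "experiment table under any per-row convention"),
    ]

    # abundance means are over all 14 rows (below-detection assays still
    # carry real abundance measurements); uncountable prey rows drop out
    all_rows = ref
    prok = all_rows["prok_cells_ml"]
    euk = all_rows["euk_cells_ml"]
    vent_all = all_rows["habitat"] == "vent"
    for item, mask, series, printed, expected, note in [
            ("vent", vent_all, prok, "1.4e5", "PASS", ""),
            ("nonvent", ~vent_all, prok, "3.5e4", "PASS", ""),
            ("piccard_vent", vent_all & (all_rows["vent_field"] == "Piccard"),
             prok, "1.9e5", "PASS", ""),
            ("vondamm_vent", vent_all & (all_rows["vent_field"] == "VonDamm"),
             prok, "7.0e4", "PASS", ""),
    ]:
        rows.append(_audit_row("group_means", item, "prok_mean", printed,
                               float(series[mask].dropna().mean()),
                               GROUP_TOL, expected=expected, note=note))
    euk_note = ("reported group-average eukaryote abundance is not "
                "recomputable from the experiment table under any per-row "
                "convention")
    for item, mask, printed, expected in [
            ("nonvent", ~vent_all, "1.1e2", "PASS"),
            ("piccard_vent", vent_all & (all_rows["vent_field"] == "Piccard"),
             "4.0e2", "PASS"),
            ("vent", vent_all, "3.7e2", "EXPECTED_MISMATCH"),
            ("vondamm_vent", vent_all & (all_rows["vent_field"] == "VonDamm"),
             "3.2e2", "EXPECTED_MISMATCH"),
            ("igt_vent", vent_all & (all_rows["approach"] == "igt"),
             "4.5e2", "EXPECTED_MISMATCH"),
            ("shipboard_vent", vent_all & (all_rows["approach"] == "ambient"),
             "3.3e2", "EXPECTED_MISMATCH"),
    ]:
        rows.append(_audit_row(
            "group_means", item, "euk_mean", printed,
            float(euk[mask].mean()), GROUP_TOL, expected=expected,
            note=euk_note if expected == "EXPECTED_MISMATCH" else ""))
    return rows


def _audit_biomass(ref: pd.DataFrame) -> list[dict]:
    euk = ref["euk_cells_ml"]
    vent = ref["habitat"] == "vent"
    rows = []

    def bracket(mask, factor) -> dict[str, float]:
        vals = euk[mask]
        return {"mean": population_biomass(factor, float(vals.mean())),
                "min": population_biomass(factor, float(vals.min())),
                "max": population_biomass(factor, float(vals.max()))}

    nv = bracket(~vent, NONVENT_CARBON_FACTOR_PG)
    rows += [
        _audit_row("biomass", "nonvent", "biomass_mean", "12.9", nv["mean"],
                   BIOMASS_TOL, expected="EXPECTED_MISMATCH",
                   note="per-row non-vent abundance mean gives 11.97; the "
                        "printed mean matches the plume-only abundance mean "
                        "(12.94)"),
        _audit_row("biomass", "nonvent", "biomass_max", "17.2", nv["max"],
                   BIOMASS_TOL),
        _audit_row("biomass", "nonvent", "biomass_min", "8.7", nv["min"],
                   BIOMASS_TOL),
    ]
    vent_note = ("published vent biomass used unpublished per-experiment "
                 "carbon factors; recomputed here with the single published "
                 "vent factor 400.8 pg C cell^-1")
    for item, mask, printed in [
            ("vent", vent, {"mean": "172.2", "max": "391.8", "min": "38.1"}),
            ("piccard_vent", vent & (ref["vent_field"] == "Piccard"),
             {"mean": "165.4", "max": "217.7", "min": "95.8"}),
            ("vondamm_vent", vent & (ref["vent_field"] == "VonDamm"),
             {"mean": "175.6", "max": "391.8", "min": "38.1"}),
            ("shipboard_vent", vent & (ref["approach"] == "ambient"),
             {"mean": "127.2", "max": "188.7", "min": "38.1"}),
            ("igt_vent", vent & (ref["approach"] == "igt"),
             {"mean": "224.9", "max": "391.8", "min": "145.1"}),
    ]:
        b = bracket(mask, VENT_CARBON_FACTOR_PG)
        for stat in ("mean", "max", "min"):
            rows.append(_audit_row("biomass", item, f"biomass_{stat}",
                                   printed[stat], b[stat], BIOMASS_TOL,
                                   expected="EXPECTED_MISMATCH",
                                   note=vent_note))
    return rows


def _audit_consumption(ref: pd.DataFrame, constants: Constants) -> list[dict]:
    usable = ref[(ref["status"] == "detected")].copy()
    fg = constants.prey_carbon_fg
    usable["clearance_pg"] = usable["specific_printed"] * fg * 1e-3
    usable["daily_ug"] = usable["grazing_printed"] * fg * 24 * 1e-6
    usable["hourly_pg"] = usable["grazing_printed"] * fg * 1e-3
    vent = usable["habitat"] == "vent"

    def stats(mask, col) -> dict[str, float]:
        vals = usable.loc[mask, col]
        return {"mean": float(vals.mean()), "min": float(vals.min()),
                "max": float(vals.max())}

    rows = []
    # hourly prey-carbon uptake reported in the running text
    rows += [
        _audit_row("consumption", "nonvent", "hourly_pg_c_ml_hr", "5.6",
                   stats(~vent, "hourly_pg")["mean"], CONSUMPTION_TOL),
        _audit_row("consumption", "shipboard_vent", "hourly_pg_c_ml_hr",
                   "209", stats(vent & (usable["approach"] == "ambient"),
                                "hourly_pg")["mean"], CONSUMPTION_TOL),
        _audit_row("consumption", "igt_vent", "hourly_pg_c_ml_hr", "980",
                   stats(vent & (usable["approach"] == "igt"),
                         "hourly_pg")["mean"], CONSUMPTION_TOL),
    ]

    def block(item, mask, clearance_printed, daily_printed,
              clearance_expected="PASS", daily_expected="PASS"):
        c, d = stats(mask, "clearance_pg"), stats(mask, "daily_ug")
        out = []
        for stat in ("mean", "min", "max"):
            out.append(_audit_row(
                "consumption", item, f"clearance_pg_c_{stat}",
                clearance_printed[stat], c[stat], CONSUMPTION_TOL,
                expected=clearance_expected,
                note=_SWAP_NOTE if clearance_expected != "PASS" else ""))
        for stat in ("mean", "min", "max"):
            out.append(_audit_row(
                "consumption", item, f"daily_ug_c_{stat}",
                daily_printed[stat], d[stat], CONSUMPTION_TOL,
                expected=daily_expected,
                note=_SWAP_NOTE if daily_expected != "PASS" else ""))
        return out

    rows += block("vent", vent,
                  {"mean": "1.20", "min": "0", "max": "3.9"},
                  {"mean": "14.27", "min": "0.24", "max": "35.68"})
    nonvent_rows = block(
        "nonvent", ~vent,
        {"mean": "0.10", "min": "0", "max": "0.1"},
        {"mean": "0.13", "min": "0.05", "max": "0.26"})
    # the printed non-vent mean clearance (0.10) is not consistent with the
    # printed specific-grazing column (which gives 0.06); flag just that cell
    nonvent_rows[0] = _audit_row(
        "consumption", "nonvent", "clearance_pg_c_mean", "0.10",
        nonvent_rows[0]["computed"], CONSUMPTION_TOL,
        expected="EXPECTED_MISMATCH",
        note="printed mean is not consistent with the printed "
             "specific-grazing column (0.06) under any rounding")
    rows += nonvent_rows
    rows += block("piccard_vent", vent & (usable["vent_field"] == "Piccard"),
                  {"mean": "2.50", "min": "1.1", "max": "3.9"},
                  {"mean": "9.39", "min": "0.24", "max": "32.75"},
                  daily_expected="EXPECTED_MISMATCH")
    rows += block("vondamm_vent", vent & (usable["vent_field"] == "VonDamm"),
                  {"mean": "0.50", "min": "0", "max": "1.4"},
                  {"mean": "24.04", "min": "12.4", "max": "35.68"},
                  daily_expected="EXPECTED_MISMATCH")
    rows += block("shipboard_vent", vent & (usable["approach"] == "ambient"),
                  {"mean": "1.86", "min": "0.26", "max": "3.86"},
                  {"mean": "23.53", "min": "2.17", "max": "35.68"},
                  clearance_expected="EXPECTED_MISMATCH",
                  daily_expected="EXPECTED_MISMATCH")
    rows += block("igt_vent", vent & (usable["approach"] == "igt"),
                  {"mean": "0.49", "min": "0.02", "max": "1.14"},
                  {"mean": "5.02", "min": "0.24", "max": "12.4"},
                  clearance_expected="EXPECTED_MISMATCH",
                  daily_expected="EXPECTED_MISMATCH")
    return rows


def reproduce_tables(constants: Constants = DEFAULT_CONSTANTS,
                     ) -> dict[str, pd.DataFrame]:
    """One-call reproduction of the campaign's derived tables.

    Returns a dict of DataFrames:

    ``rates``
        Full-precision rate chain per experiment, recomputed from the
        printed clearance.
    ``group_summary``
        Detected-only grazing-rate summaries by habitat/field/approach.
    ``biomass``
        Biomass brackets per comparison group, at the published group
        carbon factors.
    ``budget``
        Carbon-consumption statistics per comparison group.
    ``audit``
        Printed-vs-recomputed report, one row per published cell, with
        PASS / FAIL / EXPECTED_MISMATCH / OUT_OF_SCOPE status.
    """
    ref = reference_frame(constants)
    rates = _derived_rates(ref, constants)

    summaries = []
    summarizable = rates[rates["status"] != "na"]
    for by, vent_only in [("vent_nonvent", False), ("field", True),
                          ("approach", True)]:
        s = summarize(summarizable, by=by, vent_only=vent_only)
        s.insert(0, "grouping", by + ("_vent_only" if vent_only else ""))
        summaries.append(s)
    group_summary = pd.concat(summaries, ignore_index=True)

    euk = ref["euk_cells_ml"]
    vent = ref["habitat"] == "vent"
    biomass_rows = []
    for item, mask, factor in [
            ("nonvent", ~vent, NONVENT_CARBON_FACTOR_PG),
            ("vent", vent, VENT_CARBON_FACTOR_PG),
            ("piccard_vent", vent & (ref["vent_field"] == "Piccard"),
             VENT_CARBON_FACTOR_PG),
            ("vondamm_vent", vent & (ref["vent_field"] == "VonDamm"),
             VENT_CARBON_FACTOR_PG),
            ("shipboard_vent", vent & (ref["approach"] == "ambient"),
             VENT_CARBON_FACTOR_PG),
            ("igt_vent", vent & (ref["approach"] == "igt"),
             VENT_CARBON_FACTOR_PG)]:
        vals = euk[mask]
        biomass_rows.append({
            "group": item, "carbon_factor_pg": factor, "n": int(mask.sum()),
            "biomass_mean_ug_l": population_biomass(factor,
                                                    float(vals.mean())),
            "biomass_min_ug_l": population_biomass(factor, float(vals.min())),
            "biomass_max_ug_l": population_biomass(factor, float(vals.max())),
        })
    biomass = pd.DataFrame(biomass_rows)

    from .carbon import consumption_budget
    budget_rows = []
    detected = rates[rates["status"] == "detected"]
    for item, mask in [
            ("vent", detected["habitat"] == "vent"),
            ("nonvent", detected["habitat"] != "vent"),
            ("piccard_vent", (detected["habitat"] == "vent")
             & (detected["vent_field"] == "Piccard")),
            ("vondamm_vent", (detected["habitat"] == "vent")
             & (detected["vent_field"] == "VonDamm")),
            ("shipboard_vent", (detected["habitat"] == "vent")
             & (detected["approach"] == "ambient")),
            ("igt_vent", (detected["habitat"] == "vent")
             & (detected["approach"] == "igt"))]:
        b = consumption_budget(detected[mask], group_key=item,
                               constants=constants)
        budget_rows.append({
            "group": item, "n_detected": b.n_detected,
            **{f"hourly_pg_c_{k}": v
               for k, v in b.consumption_pg_c_ml_hr.items()},
            **{f"daily_ug_c_{k}": v
               for k, v in b.consumption_ug_c_l_day.items()},
            **{f"clearance_pg_c_{k}": v
               for k, v in b.clearance_pg_c_per_grazer.items()},
            "fraction_of_pp_max": b.fraction_of_pp[0],
            "fraction_of_pp_min": b.fraction_of_pp[1],
        })
    budget = pd.DataFrame(budget_rows)

    audit_rows = (_audit_rate_chain(ref, constants)
                  + _audit_group_means(ref)
                  + _audit_biomass(ref)
                  + _audit_consumption(ref, constants))
    audit_rows.append({
        "section": "community", "item": "shared_asvs_across_fields",
        "quantity": "n_shared_asvs", "printed": 1500.0, "computed": np.nan,
        "rel_err": np.nan, "status": "OUT_OF_SCOPE",
        "note": "requires the deposited amplicon sequence dataset; the "
                "shared-ASV operation is validated on synthetic tables"})
    audit = pd.DataFrame(audit_rows)
    return {"rates": rates, "group_summary": group_summary,
            "biomass": biomass, "budget": budget, "audit": audit}
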