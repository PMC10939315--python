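"""ASV-table utilities for the 18S rRNA amplicon side of the study.

Works on a samples x ASVs count matrix with PR2-style ranked taxonomy and
per-sample metadata (habitat, in-situ vs final-timepoint role, site, vent
field).  Provides the habitat-distribution classification (vent-only vs
cosmopolitan), the captured-community intersection between in-situ and
grazing-incubation samples, the centered log-ratio transform used ahead of
ordination, and the raw count-increase enrichment heuristic.  The
beta-binomial differential-abundance model (corncob) is out of scope; the
enrichment output reserves a column for its externally fitted coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AsvTable", "classify_distribution", "shared_asvs",
           "clr_transform", "group_enrichment"]

HABITATS = ("vent", "plume", "background")


@dataclass
class AsvTable:
    """Samples x ASVs counts with taxonomy and sample metadata.

    ``counts``: integer DataFrame, samples as rows, ASVs as columns.
    ``taxonomy``: indexed by asv_id with at least the ranks used for
    grouping (e.g. ``division``, ``family``).
    ``sample_meta``: indexed by sample_id with columns ``habitat``
    (vent|plume|background), ``role`` (in_situ|tf), ``site``,
    ``vent_field``, and optionally ``pairing_id`` linking a tf sample to
    its in-situ partner.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate ASV ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if len(self.sample_meta):
            missing = self.counts.index.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"samples without metadata: {list(missing)}")
            bad = set(self.sample_meta["habitat"]) - set(HABITATS)
            if bad:
                raise ValueError(f"unknown habitat(s) {bad}")


def classify_distribution(t: AsvTable) -> pd.Series:
    """Classify each ASV by habitat occupancy.

    ``vent_only``: nonzero counts in vent samples only.  ``cosmopolitan``:
    nonzero in vent AND plume AND background samples.  Every other nonzero
    occupancy pattern is ``other``.  ASVs with zero total count have no
    defined distribution and are absent from the result.
    """
    habitats = t.sample_meta.loc[t.counts.index, "habitat"]
    present = {h: (t.counts[habitats.to_numpy() == h] > 0).any(axis=0)
               for h in HABITATS}
    nonzero = t.counts.sum(axis=0) > 0
    out = pd.Series("other", index=t.counts.columns[nonzero], dtype=object)
    vent, plume, bkg = (present[h][nonzero] for h in HABITATS)
    out[vent & ~plume & ~bkg] = "vent_only"
    out[vent & plume & bkg] = "cosmopolitan"
    out.name = "distribution"
    return out


def _pairing_from_meta(t: AsvTable) -> dict[str, str]:
    """Derive a tf -> in_situ sample map from ``pairing_id`` metadata."""
    meta = t.sample_meta
    if "pairing_id" not in meta.columns:
        raise ValueError("sample_meta has no pairing_id column")
    pairing: dict[str, str] = {}
    for pid, grp in meta.dropna(subset=["pairing_id"]).groupby("pairing_id"):
        tf = grp.index[grp["role"] == "tf"]
        insitu = grp.index[grp["role"] == "in_situ"]
        if len(tf) != 1 or len(insitu) != 1:
            raise ValueError(
                f"pairing {pid!r} must link exactly one tf sample to one "
                "in_situ sample")
        pairing[tf[0]] = insitu[0]
    return pairing


def _check_pairing(t: AsvTable, pairing: dict[str, str] | None,
                   ) -> dict[str, str]:
    if pairing is None:
        pairing = _pairing_from_meta(t)
    for tf, insitu in pairing.items():
        if tf not in t.counts.index or insitu not in t.counts.index:
            raise ValueError(f"pairing refers to unknown sample(s): "
                             f"{tf!r} -> {insitu!r}")
    tf_samples = (t.sample_meta.index[t.sample_meta["role"] == "tf"]
                  if len(t.sample_meta) else pd.Index([]))
    unpaired = set(tf_samples) - set(pairing)
    if unpaired:
        raise ValueError(f"unpaired tf sample(s): {sorted(unpaired)}")
    return pairing


def shared_asvs(t: AsvTable, pairing: dict[str, str] | None = None,
                ) -> dict[str, set[str]]:
    """ASVs captured by each grazing incubation.

    An ASV present (count >= 1) in both a final-timepoint (tf) sample and
    its paired in-situ sample is considered a member of the captured
    protistan community.  ``pairing`` maps tf sample id -> in_situ sample
    id; when omitted it is derived from the ``pairing_id`` metadata.
    """
    pairing = _check_pairing(t, pairing)
    out: dict[str, set[str]] = {}
    for tf, insitu in pairing.items():
        both = (t.counts.loc[tf] > 0) & (t.counts.loc[insitu] > 0)
        out[tf] = set(t.counts.columns[both])
    return out


def clr_transform(t: AsvTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of the count matrix.

    Per sample, x -> log(x + pseudocount) - mean_over_ASVs log(x +
    pseudocount); each output row sums to zero.  The pseudocount (default
    1, appropriate for integer counts) keeps zeros finite and is exposed
    because the choice is a modelling decision, not data.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if t.counts.empty:
        raise ValueError("empty ASV table")
    logs = np.log(t.counts.to_numpy(dtype=float) + pseudocount)
    centered = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=t.counts.index,
                        columns=t.counts.columns)


def group_enrichment(t: AsvTable, pairing: dict[str, str] | None = None,
                     rank: str = "family") -> pd.DataFrame:
    """Count-increase enrichment of taxonomic groups during incubations.

    For each group at ``rank``, totals sequences and distinct ASVs across
    the paired in-situ samples versus the tf samples; a group is enriched
    if the sequence total and/or the ASV count increased.  Groups absent
    from both sides are omitted.  The ``corncob_coefficient`` column is a
    reserved slot for an externally fitted beta-binomial coefficient.
    """
    if rank not in t.taxonomy.columns:
        raise KeyError(f"rank {rank!r} not in taxonomy")
    pairing = _check_pairing(t, pairing)
    tf_ids = list(pairing)
    insitu_ids = [pairing[s] for s in tf_ids]
    groups = t.taxonomy[rank]
    rows = []
    for group, asvs in groups.groupby(groups):
        cols = [a for a in asvs.index if a in t.counts.columns]
        insitu_counts = t.counts.loc[insitu_ids, cols]
        tf_counts = t.counts.loc[tf_ids, cols]
        seq_insitu = int(insitu_counts.to_numpy().sum())
        seq_tf = int(tf_counts.to_numpy().sum())
        asv_insitu = int(((insitu_counts.sum(axis=0)) > 0).sum())
        asv_tf = int(((tf_counts.sum(axis=0)) > 0).sum())
        if seq_insitu == 0 and seq_tf == 0:
            continue
        rows.append({
            "group": group,
            "seq_in_situ": seq_insitu, "seq_tf": seq_tf,
            "seq_delta": seq_tf - seq_insitu,
            "asv_in_situ": asv_insitu, "asv_tf": asv_tf,
            "asv_delta": asv_tf - asv_insitu,
            "enriched": (seq_tf > seq_insitu) or (asv_tf > asv_insitu),
            "corncob_coefficient": np.nan,
        })
    return pd.DataFrame(rows)
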