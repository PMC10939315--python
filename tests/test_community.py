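import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flpgraze.community import (AsvTable, classify_distribution,
                                clr_transform, group_enrichment, shared_asvs)
from flpgraze.synthetic import simulate_asv_table


def make_table(counts, habitats=None, roles=None, pairing=None,
               taxonomy=None):
    counts = pd.DataFrame(counts).T  # input dict asv -> per-sample counts
    counts.index.name = "asv_id"
    counts = counts.T
    n = len(counts.index)
    meta = pd.DataFrame({
        "habitat": habitats or ["vent"] * n,
        "role": roles or ["in_situ"] * n,
        "site": "s", "vent_field": "VonDamm",
    }, index=counts.index)
    if pairing:
        meta["pairing_id"] = pairing
    tax = (pd.DataFrame(taxonomy, index=counts.columns)
           if taxonomy else pd.DataFrame(index=counts.columns))
    return AsvTable(counts=counts, taxonomy=tax, sample_meta=meta)


class TestClassifyDistribution:
    # all 7 nonzero occupancy patterns over (vent, plume, background)
    @pytest.mark.parametrize("pattern, expected", [
        ((1, 0, 0), "vent_only"),
        ((1, 1, 1), "cosmopolitan"),
        ((0, 1, 0), "other"),
        ((0, 0, 1), "other"),
        ((1, 1, 0), "other"),
        ((1, 0, 1), "other"),
        ((0, 1, 1), "other"),
    ])
    def test_every_occupancy_pattern(self, pattern, expected):
        t = make_table({"asv1": {"v1": pattern[0] * 5, "p1": pattern[1] * 3,
                                 "b1": pattern[2] * 2}},
                       habitats=["vent", "plume", "background"])
        assert classify_distribution(t)["asv1"] == expected

    def test_zero_total_asv_absent_from_result(self):
        t = make_table({"a": {"v1": 1, "p1": 0, "b1": 0},
                        "ghost": {"v1": 0, "p1": 0, "b1": 0}},
                       habitats=["vent", "plume", "background"])
        result = classify_distribution(t)
        assert "ghost" not in result.index
        assert set(result.index) == {"a"}

    def test_partition_of_nonzero_asvs(self):
        table, _ = simulate_asv_table(n_asvs=200, vent_only_fraction=0.25,
                                      cosmopolitan_fraction=0.4, seed=3)
        result = classify_distribution(table)
        nonzero = (table.counts.sum(axis=0) > 0).sum()
        assert len(result) == nonzero
        assert set(result.unique()) <= {"vent_only", "cosmopolitan", "other"}


class TestSharedAsvs:
    def paired_table(self, insitu_counts, tf_counts):
        return make_table(
            {a: {"s_in": insitu_counts.get(a, 0), "s_tf": tf_counts.get(a, 0)}
             for a in set(insitu_counts) | set(tf_counts)},
            habitats=["vent", "vent"], roles=["in_situ", "tf"],
            pairing=["p1", "p1"])

    def test_identical_patterns_share_everything(self):
        t = self.paired_table({"a": 2, "b": 1}, {"a": 5, "b": 9})
        assert shared_asvs(t) == {"s_tf": {"a", "b"}}

    def test_disjoint_patterns_share_nothing(self):
        t = self.paired_table({"a": 2}, {"b": 3})
        assert shared_asvs(t) == {"s_tf": set()}

    def test_intersection(self):
        t = self.paired_table({"a": 1, "b": 1, "c": 1},
                              {"b": 1, "c": 1, "d": 1})
        assert shared_asvs(t) == {"s_tf": {"b", "c"}}

    def test_shared_subset_of_each_member(self):
        t = self.paired_table({"a": 4, "b": 0, "c": 7}, {"a": 1, "b": 2})
        (shared,) = shared_asvs(t).values()
        assert shared <= {"a", "c"} and shared <= {"a", "b"}

    def test_unpaired_tf_sample_rejected(self):
        t = make_table({"a": {"s_in": 1, "s_tf": 1}},
                       habitats=["vent", "vent"],
                       roles=["in_situ", "tf"])
        with pytest.raises(ValueError, match="pairing"):
            shared_asvs(t)


class TestClr:
    def test_uniform_row_maps_to_zeros(self):
        t = make_table({"a": {"s1": 7}, "b": {"s1": 7}, "c": {"s1": 7}})
        assert np.allclose(clr_transform(t).loc["s1"], 0.0)

    def test_all_zero_row_maps_to_zeros(self):
        t = make_table({"a": {"s1": 0}, "b": {"s1": 0}})
        assert np.allclose(clr_transform(t, pseudocount=1.0).loc["s1"], 0.0)

    def test_frozen_example(self):
        # counts (1,3,9), pseudocount 1 -> log(2,4,10) centered
        t = make_table({"a": {"s1": 1}, "b": {"s1": 3}, "c": {"s1": 9}})
        out = clr_transform(t, pseudocount=1.0).loc["s1"]
        assert np.allclose(out, [-0.76752836, -0.07438118, 0.84190955])

    def test_matches_scikit_bio_oracle(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 200, size=(4, 8))
        t = make_table({f"a{j}": {f"s{i}": int(counts[i, j])
                                  for i in range(4)} for j in range(8)})
        ours = clr_transform(t, pseudocount=1.0)
        theirs = skbio_comp.clr(counts.astype(float) + 1.0)
        assert np.allclose(ours.to_numpy(), theirs)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.lists(st.integers(0, 500), min_size=3, max_size=3),
                    min_size=1, max_size=5))
    def test_rows_sum_to_zero(self, rows):
        t = make_table({f"a{j}": {f"s{i}": rows[i][j]
                                  for i in range(len(rows))}
                        for j in range(3)})
        out = clr_transform(t)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_scale_invariance_in_small_pseudocount_limit(self):
        t1 = make_table({"a": {"s1": 10}, "b": {"s1": 20}, "c": {"s1": 40}})
        t2 = make_table({"a": {"s1": 30}, "b": {"s1": 60}, "c": {"s1": 120}})
        eps = 1e-9
        assert np.allclose(clr_transform(t1, eps).to_numpy(),
                           clr_transform(t2, eps).to_numpy(), atol=1e-6)

    def test_invalid_inputs(self):
        t = make_table({"a": {"s1": 1}})
        with pytest.raises(ValueError):
            clr_transform(t, pseudocount=0.0)


class TestGroupEnrichment:
    def table(self, insitu, tf):
        taxonomy = {"family": {"a1": "ciliate", "a2": "ciliate",
                               "a3": "dino", "a4": "dino"}}
        counts = {a: {"s_in": insitu.get(a, 0), "s_tf": tf.get(a, 0)}
                  for a in ("a1", "a2", "a3", "a4")}
        return make_table(counts, habitats=["vent", "vent"],
                          roles=["in_situ", "tf"], pairing=["p1", "p1"],
                          taxonomy=taxonomy)

    def test_sequence_increase_is_enrichment(self):
        t = self.table({"a1": 100}, {"a1": 150})
        out = group_enrichment(t).set_index("group")
        assert out.loc["ciliate", "enriched"]
        assert out.loc["ciliate", "seq_delta"] == 50

    def test_no_change_is_not_enrichment(self):
        t = self.table({"a1": 100}, {"a1": 100})
        out = group_enrichment(t).set_index("group")
        assert not out.loc["ciliate", "enriched"]

    def test_asv_gain_overrides_sequence_loss(self):
        # sequences 100 -> 90 but ASVs 1 -> 2: the and/or rule fires
        t = self.table({"a1": 100}, {"a1": 45, "a2": 45})
        out = group_enrichment(t).set_index("group")
        assert out.loc["ciliate", "enriched"]
        assert out.loc["ciliate", "asv_delta"] == 1

    def test_group_absent_from_both_sides_omitted(self):
        t = self.table({"a1": 10}, {"a1": 12})
        assert "dino" not in set(group_enrichment(t)["group"])

    def test_reserved_corncob_column_present(self):
        t = self.table({"a1": 10}, {"a1": 12})
        assert "corncob_coefficient" in group_enrichment(t).columns

    def test_unknown_rank_rejected(self):
        t = self.table({"a1": 10}, {"a1": 12})
        with pytest.raises(KeyError):
            group_enrichment(t, rank="genus")
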