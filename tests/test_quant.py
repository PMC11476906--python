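"""Alignment filtering, insert counting/allocation, and normalization."""

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedncycle.quant import (
    AlignmentRow,
    count_inserts,
    filter_alignments,
    length_normalize,
    aggregate_ko,
    per_cell_normalize,
)

from conftest import alignment_frame


def brute_force_allocation(pairs):
    """Independent reference implementation of the counting rule.

    Plain dict-and-loop enumeration: unique inserts add 1; ambiguous
    inserts split proportionally to their targets' unique counts, equally
    if those are all zero.
    """
    targets = defaultdict(set)
    for insert, gene in pairs:
        targets[insert].add(gene)
    unique = defaultdict(float)
    for insert, genes in targets.items():
        if len(genes) == 1:
            unique[next(iter(genes))] += 1.0
    counts = dict(unique)
    for insert, genes in targets.items():
        if len(genes) == 1:
            continue
        total = sum(unique.get(g, 0.0) for g in genes)
        for g in genes:
            w = unique.get(g, 0.0) / total if total > 0 else 1.0 / len(genes)
            counts[g] = counts.get(g, 0.0) + w
    return counts


class TestFilterAlignments:
    @pytest.mark.parametrize(
        "pct,aligned,kept",
        [(95.0, 45, True), (94.9, 100, False), (99.0, 44, False), (100.0, 150, True)],
    )
    def test_inclusive_identity_and_length_cutoffs(self, pct, aligned, kept):
        rows = [AlignmentRow("i", "g", pct, aligned)]
        assert (len(filter_alignments(rows)) == 1) is kept

    def test_empty_in_empty_out_and_dataframe_path(self):
        assert filter_alignments([]) == []
        df = alignment_frame([("a", "g")], pct=94.0)
        assert filter_alignments(df).empty


class TestCountInserts:
    def test_proportional_allocation_example(self):
        # uniques g1:3, g2:1; one ambiguous insert against both
        pairs = [("a", "g1"), ("b", "g1"), ("c", "g1"), ("d", "g2"),
                 ("x", "g1"), ("x", "g2")]
        cp = count_inserts(alignment_frame(pairs))
        assert cp.counts["g1"] == pytest.approx(3.75)
        assert cp.counts["g2"] == pytest.approx(1.25)
        assert cp.counts.sum() == pytest.approx(5.0)

    def test_equal_split_when_no_unique_counts(self):
        cp = count_inserts(alignment_frame([("x", "g1"), ("x", "g2")]))
        assert cp.counts["g1"] == cp.counts["g2"] == pytest.approx(0.5)

    def test_discard_policy_drops_orphan_ambiguous(self):
        cp = count_inserts(
            alignment_frame([("x", "g1"), ("x", "g2")]),
            zero_unique_policy="discard",
        )
        assert cp.counts.sum() == 0
        assert cp.n_discarded == 1
        assert cp.n_inserts == 0

    def test_only_uniques_equals_raw_counts(self):
        pairs = [("a", "g1"), ("b", "g1"), ("c", "g2")]
        cp = count_inserts(alignment_frame(pairs))
        assert cp.counts.to_dict() == {"g1": 2.0, "g2": 1.0}

    def test_duplicate_pairs_deduplicated_with_warning(self):
        pairs = [("a", "g1"), ("a", "g1"), ("b", "g2")]
        with pytest.warns(UserWarning, match="deduplicated"):
            cp = count_inserts(alignment_frame(pairs))
        assert cp.counts.sum() == pytest.approx(2.0)

    def test_allocation_is_scale_free(self):
        # tripling unique counts of both targets leaves the split unchanged
        base = [("u%d" % i, "g1") for i in range(3)] + [("v0", "g2")]
        scaled = [("u%d" % i, "g1") for i in range(9)] + [
            ("v%d" % i, "g2") for i in range(3)
        ]
        amb = [("x", "g1"), ("x", "g2")]
        c1 = count_inserts(alignment_frame(base + amb)).counts
        c2 = count_inserts(alignment_frame(scaled + amb)).counts
        split1 = c1["g1"] - 3, c1["g2"] - 1
        split2 = c2["g1"] - 9, c2["g2"] - 3
        assert split1 == pytest.approx(split2)

    @given(st.data())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle_on_small_tables(self, data):
        n_genes = data.draw(st.integers(1, 6))
        n_inserts = data.draw(st.integers(1, 20))
        genes = [f"g{i}" for i in range(n_genes)]
        pairs = []
        for i in range(n_inserts):
            tgts = data.draw(
                st.sets(st.sampled_from(genes), min_size=1, max_size=n_genes)
            )
            pairs.extend((f"i{i}", g) for g in sorted(tgts))
        mine = count_inserts(alignment_frame(pairs)).counts.to_dict()
        ref = brute_force_allocation(pairs)
        assert set(mine) == set(ref)
        for g in ref:
            assert mine[g] == pytest.approx(ref[g], abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_total_count_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 500))
        genes = [f"g{i}" for i in range(int(rng.integers(1, 30)))]
        pairs = []
        for i in range(n):
            k = 1 + (rng.random() < 0.3) * int(rng.integers(1, 3))
            for g in rng.choice(genes, size=min(k, len(genes)), replace=False):
                pairs.append((f"i{i}", g))
        cp = count_inserts(alignment_frame(pairs))
        assert cp.counts.sum() == pytest.approx(cp.n_inserts, rel=1e-9)
        assert cp.n_inserts == n


class TestNormalization:
    def test_length_normalize_arithmetic(self, tiny_catalog):
        cp = count_inserts(
            alignment_frame([(f"i{k}", "nosZ_1") for k in range(19)]),
            sample_id="s",
        )
        ab = length_normalize(cp, tiny_catalog)
        assert ab.values["nosZ_1"] == pytest.approx(19 / 1900)

    def test_length_normalize_missing_gene(self, tiny_catalog):
        cp = count_inserts(alignment_frame([("a", "nope")]))
        with pytest.raises(KeyError, match="nope"):
            length_normalize(cp, tiny_catalog)

    def test_doubling_length_halves_abundance(self, tiny_catalog):
        cp = count_inserts(alignment_frame([("a", "amoA_1"), ("b", "amoA_2")]))
        ab = length_normalize(cp, tiny_catalog)
        # same counts; amoA_2 is longer so its abundance is smaller
        assert ab.values["amoA_1"] * 750 == pytest.approx(ab.values["amoA_2"] * 800)

    def test_aggregate_ko_sums_and_reports_unannotated(self, tiny_catalog):
        from sedncycle.quant import AbundanceProfile

        ab = AbundanceProfile(
            "s", "metaG",
            pd.Series({"amoA_1": 0.0025, "amoA_2": 0.0005, "nosZ_1": 0.001}),
        )
        ko = aggregate_ko(ab, tiny_catalog)
        assert ko.values["K10944"] == pytest.approx(0.003)
        assert ko.values["K00376"] == pytest.approx(0.001)
        assert ko.unannotated_mass == 0.0

    def test_aggregate_ko_empty(self, tiny_catalog):
        from sedncycle.quant import AbundanceProfile

        ko = aggregate_ko(AbundanceProfile("s", "metaG", pd.Series(dtype=float)),
                          tiny_catalog)
        assert ko.values.empty

    def test_per_cell_arithmetic_and_depth_invariance(self):
        from sedncycle.quant import AbundanceProfile

        ab = AbundanceProfile("s", "metaG", pd.Series({"k": 0.003}))
        markers = [0.25] * 10
        pc = per_cell_normalize(ab, markers)
        assert pc.values["k"] == pytest.approx(0.012)
        # uniform depth rescaling cancels exactly
        ab10 = AbundanceProfile("s", "metaG", ab.values * 10)
        pc10 = per_cell_normalize(ab10, [m * 10 for m in markers])
        assert pc10.values["k"] == pytest.approx(pc.values["k"], abs=1e-15)

    def test_marker_median_zero_and_count_checks(self):
        from sedncycle.quant import AbundanceProfile

        ab = AbundanceProfile("s", "metaG", pd.Series({"k": 1.0}))
        with pytest.raises(ValueError, match="marker median zero"):
            per_cell_normalize(ab, [0.0] * 10)
        with pytest.raises(ValueError, match="marker"):
            per_cell_normalize(ab, [1.0] * 7)
        with pytest.warns(UserWarning):
            pc = per_cell_normalize(ab, [2.0] * 7, allow_partial=True)
        assert pc.marker_median == 2.0
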