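"""Transitions-only distances, diversity, barcoding gap, NJ trees."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivoryid import (
    PairwiseComparison,
    barcoding_gap,
    check_monophyly,
    compare_pair,
    distance_matrix,
    distance_summary,
    k2p_ts,
    nj_tree,
    nucleotide_diversity,
    p_distance_ts,
)
from ivoryid import tables as T
from ivoryid.distances import GapSummary, bootstrap_support
from ivoryid.errors import (
    AlignmentError,
    GapUndefinedError,
    InsufficientDataError,
    SaturationError,
    UndefinedDistanceError,
    ValidationError,
)
from ivoryid.panel import rcrs_to_fragment_index


def _variant(panel, species, clade, states):
    """The group haplotype whose variants carry the given rCRS states."""
    for h in panel.by_species(species, clade):
        if all(h.variants[p] == b for p, b in states.items()):
            return h
    raise LookupError(states)


class TestComparePair:
    def test_identical_sequences(self):
        c = compare_pair("ACGT" * 29, "ACGT" * 29)
        assert (c.compared_sites, c.ts_diffs, c.tv_diffs) == (116, 0, 0)

    def test_pairwise_deletion_excludes_ambiguity(self):
        c = compare_pair("ACGTN", "ACTT-")
        assert c.compared_sites == 4  # the N/- column is dropped
        assert (c.ts_diffs, c.tv_diffs) == (0, 1)

    def test_emax_vs_sclade_with_g15210(self, panel):
        """Eight fixed transitions separate the Asian elephant from the
        S-clade haplotype carrying G at rCRS 15210."""
        emax = panel.by_species(T.ASIAN_ELEPHANT)[0]
        sclade = _variant(panel, T.SAVANNA_ELEPHANT, "S",
                          {15210: "G"})
        c = compare_pair(emax.sequence, sclade.sequence)
        assert (c.ts_diffs, c.tv_diffs, c.compared_sites) == (8, 0, 115)

    def test_emax_vs_mammoth_with_t15190(self, panel):
        emax = panel.by_species(T.ASIAN_ELEPHANT)[0]
        mammoth = _variant(panel, T.WOOLLY_MAMMOTH, None,
                           {15190: "T"})
        c = compare_pair(emax.sequence, mammoth.sequence)
        assert c.ts_diffs == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            compare_pair("ACGT", "ACG")

    def test_transition_oracle_over_variant_positions(self, panel):
        """ts counts equal brute-force comparison restricted to the
        tabulated positions: the shared background contributes zero."""
        ts_sets = ({"A", "G"}, {"C", "T"})
        for a, b in itertools.combinations(panel.haplotypes, 2):
            expected = sum(
                1
                for pos in T.TABLE1_POSITIONS
                if a.variants[pos] != b.variants[pos]
                and {a.variants[pos], b.variants[pos]} in ts_sets
            )
            assert compare_pair(a.sequence, b.sequence).ts_diffs \
                == expected


class TestDistanceModels:
    def test_zero_distance(self):
        c = PairwiseComparison(116, 0, 0)
        assert p_distance_ts(c) == 0.0
        assert k2p_ts(c) == 0.0

    @pytest.mark.parametrize("ts,p_pct,k2p_pct", [
        (8, 6.96, 7.49),   # published overall interspecific maxima
        (5, 4.35, 4.55),   # E. maximus vs mammoth upper bound
        (7, 6.09, 6.49),
    ])
    def test_known_values_over_115_sites(self, ts, p_pct, k2p_pct):
        c = PairwiseComparison(115, ts, 0)
        assert round(p_distance_ts(c) * 100, 2) == p_pct
        assert round(k2p_ts(c) * 100, 2) == k2p_pct

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_ts(PairwiseComparison(100, 50, 0))

    def test_no_comparable_sites_raises(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance_ts(PairwiseComparison(0, 0, 0))

    @given(st.integers(0, 99))
    @settings(derandomize=True, max_examples=60)
    def test_k2p_dominates_p_without_transversions(self, ts):
        """In the marker's transitions-only regime the K2P correction
        only stretches distances: K2P >= p, with equality exactly at
        zero divergence."""
        c = PairwiseComparison(200, ts, 0)
        k, p = k2p_ts(c), p_distance_ts(c)
        assert k >= p - 1e-12
        assert (k == p) == (ts == 0)

    def test_small_p_limit(self):
        c = PairwiseComparison(10_000, 1, 0)  # P = 1e-4
        assert k2p_ts(c) / p_distance_ts(c) == pytest.approx(
            1.0, rel=1e-3)

    def test_symmetry_and_zero_diagonal(self, panel):
        seqs = [h.sequence for h in panel.haplotypes[:6]]
        ids = [h.haplotype_id for h in panel.haplotypes[:6]]
        m = distance_matrix(seqs, ids)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)


class TestDistanceSummary:
    def test_singleton_class_reports_degenerate_range(self, panel):
        """The invariant Asian elephant prints as a 0-0 diagonal."""
        seqs, labels = panel.distance_set()
        s = distance_summary(seqs, labels, model="k2p")
        row = s.intra.loc[T.ASIAN_ELEPHANT]
        assert (row["min"], row["max"]) == (0.0, 0.0)

    def test_two_identical_sequences_in_one_species(self):
        s = distance_summary(["ACGT" * 29] * 2 + ["AAGT" * 29],
                             ["sp1", "sp1", "sp2"])
        assert s.intra.loc["sp1", ["min", "max"]].tolist() == [0, 0]

    def test_emax_vs_sclade_extremes_match_published(self, panel):
        """The species pair behind the published maxima spans 7-8
        transitions: 6.49-7.49% K2P and 6.96% maximum p-distance."""
        seqs, labels = panel.distance_set()
        for model, lo, hi in (("k2p", 6.49, 7.49), ("p", 6.09, 6.96)):
            s = distance_summary(seqs, labels, model=model)
            row = s.inter.loc["|".join(sorted(
                (T.ASIAN_ELEPHANT, T.SAVANNA_ELEPHANT)))]
            assert round(row["min"] * 100, 2) == lo
            assert round(row["max"] * 100, 2) == hi

    def test_permutation_invariance(self, panel):
        seqs, labels = panel.distance_set()
        s1 = distance_summary(seqs, labels)
        order = np.random.default_rng(0).permutation(len(seqs))
        s2 = distance_summary([seqs[i] for i in order],
                              [labels[i] for i in order])
        pd.testing.assert_frame_equal(s1.intra, s2.intra)
        pd.testing.assert_frame_equal(s1.inter, s2.inter)

    def test_too_few_sequences(self):
        with pytest.raises(InsufficientDataError):
            distance_summary(["ACGT"], ["a"])


class TestBarcodingGap:
    def test_published_gap_arithmetic(self):
        """0.89%-1.80% (K2P) and 0.87%-1.77% (p) give gaps of 0.91 and
        0.90 percentage points."""
        k2p = GapSummary(upper_intra=0.0089, lower_inter=0.0180)
        assert k2p.gap_width == pytest.approx(0.0091)
        p = GapSummary(upper_intra=0.0087, lower_inter=0.0177)
        assert p.gap_width == pytest.approx(0.0090)

    def test_zero_and_negative_gaps_reported(self):
        assert GapSummary(0.02, 0.02).gap_width == 0
        assert GapSummary(0.03, 0.01).gap_width == pytest.approx(-0.02)

    def test_gap_from_summary(self):
        s = distance_summary(
            ["A" * 50, "A" * 49 + "G", "G" * 5 + "A" * 45],
            ["sp1", "sp1", "sp2"])
        gap = barcoding_gap(s)
        assert gap.lower_inter > gap.upper_intra > 0

    def test_missing_class_raises(self):
        s = distance_summary(["ACGT", "ACGA"], ["sp1", "sp2"])
        with pytest.raises(GapUndefinedError):
            barcoding_gap(s)


class TestNucleotideDiversity:
    def test_identical_set_has_zero_diversity(self):
        d = nucleotide_diversity(["ACGT" * 29] * 4)
        assert d.pi == 0.0
        assert d.n_segregating_sites == 0

    def test_single_difference(self):
        a = "A" * 116
        b = "A" * 115 + "G"
        d = nucleotide_diversity([a, b])
        assert d.pi == pytest.approx(1 / 116)

    def test_three_sequences_brute_force(self):
        a = "A" * 116
        b = "A" * 115 + "C"   # transversions count too
        d = nucleotide_diversity([a, a, b])
        assert d.pi == pytest.approx((0 + 1 + 1) / 3 / 116)
        assert d.n_segregating_sites == 1

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            nucleotide_diversity(["ACGT"])


class TestNeighbourJoining:
    def test_three_taxa(self):
        m = pd.DataFrame(
            [[0, 2, 3], [2, 0, 3], [3, 3, 0]],
            index=list("abc"), columns=list("abc"), dtype=float)
        newick = nj_tree(m)
        assert sorted(l for l in "abc" if l in newick) == list("abc")

    def test_additive_four_taxon_recovery(self):
        """NJ recovers the generating topology and branch lengths of a
        hand-built additive matrix (tree ((a:1,b:2):1,(c:3,d:4)))."""
        import io

        import skbio

        labels = list("abcd")
        m = pd.DataFrame(
            [[0, 3, 5, 6],
             [3, 0, 6, 7],
             [5, 6, 0, 7],
             [6, 7, 7, 0]],
            index=labels, columns=labels, dtype=float)
        tree = skbio.TreeNode.read(io.StringIO(nj_tree(m)))
        tip_dist = tree.tip_tip_distances()
        for a, b in itertools.combinations(labels, 2):
            assert tip_dist[a, b] == pytest.approx(m.loc[a, b])
        splits = check_monophyly(nj_tree(m),
                                 {"a": "left", "b": "left",
                                  "c": "right", "d": "right"})
        assert splits == {"left": True, "right": True}

    def test_invalid_matrices_rejected(self):
        bad = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                           index=list("abc"), columns=list("abc"),
                           dtype=float)
        with pytest.raises(ValidationError, match="symmetric"):
            nj_tree(bad)
        with pytest.raises(ValidationError, match="3 taxa"):
            nj_tree(pd.DataFrame([[0.0]], index=["a"], columns=["a"]))


class TestMonophyly:
    def test_panel_groups_form_clades(self, panel):
        """Representative haplotypes of the four elephantid groups
        cluster into separate lineages with an outgroup present."""
        reps = panel.representative_haplotypes()
        seqs = [h.sequence for h in reps]
        ids = [h.haplotype_id for h in reps]
        labels = {h.haplotype_id: h.group for h in reps}
        # synthetic outgroup: background shifted at 12 non-variant sites
        out = list(panel.by_species(T.ASIAN_ELEPHANT)[0].sequence)
        free = [i for i in range(116)
                if i not in {rcrs_to_fragment_index(p)
                             for p in T.TABLE1_POSITIONS}][:12]
        for i in free:
            out[i] = "G"
        seqs.append("".join(out))
        ids.append("outgroup")
        labels["outgroup"] = "outgroup"
        result = check_monophyly(nj_tree(distance_matrix(seqs, ids)),
                                 labels)
        assert all(result[g] for g in T.ASSIGNMENT_GROUPS)

    def test_star_tree_singletons(self):
        newick = "(a:1,b:1,c:1,d:1);"
        result = check_monophyly(
            newick, {x: x.upper() for x in "abcd"})
        assert all(result.values())

    def test_crossing_labels_break_monophyly(self):
        newick = "((a:1,b:1):1,(c:1,d:1):1);"
        result = check_monophyly(
            newick, {"a": "L", "c": "L", "b": "R", "d": "R"})
        assert result == {"L": False, "R": False}

    def test_complement_of_terminal_edge_is_a_split(self):
        # unrooted reading: the edge to leaf a isolates {b, c, d} too
        newick = "((a:1,b:1):1,(c:1,d:1):1);"
        result = check_monophyly(
            newick, {"a": "L", "b": "R", "c": "R", "d": "R"})
        assert result == {"L": True, "R": True}

    def test_unlabelled_leaf_raises(self):
        with pytest.raises(ValidationError, match="unlabelled"):
            check_monophyly("(a:1,b:1,c:1);", {"a": "x", "b": "x"})


class TestBootstrap:
    def test_supports_are_reproducible_fractions(self, panel):
        reps = panel.representative_haplotypes()
        seqs = [h.sequence for h in reps]
        ids = [h.haplotype_id for h in reps]
        s1 = bootstrap_support(seqs, ids, replicates=25, seed=7)
        s2 = bootstrap_support(seqs, ids, replicates=25, seed=7)
        assert s1 == s2
        assert all(0.0 <= v <= 1.0 for v in s1.values())
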