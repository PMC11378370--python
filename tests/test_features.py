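"""Feature extraction: mutation classes, GC, ORF tracking, Kozak turnover."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from denovoscenario import (
    RULE_ATG,
    RULE_KOZAK,
    RULE_KOZAK_FULL,
    classify_kozak_transition,
    classify_length_change,
    classify_mutations,
    gc_content,
    induce_pair,
    locate_start,
    map_ancestral_orf,
    scan_orfs,
)
from denovoscenario.features import (
    InducedPair,
    OrfAnnotation,
    orf_start_has_kozak,
    select_overlapping_orf,
)
from denovoscenario.sequtil import revcomp


class TestInducePair:
    def test_gapless_rows_unchanged(self):
        pair = induce_pair({"x": "ACGT", "y": "AGGT"}, "x", "y")
        assert pair.older == "ACGT" and pair.younger == "AGGT"

    def test_column_gapped_in_both_removed(self):
        pair = induce_pair({"x": "AC-GT", "y": "AG-GT"}, "x", "y")
        assert pair.older == "ACGT"
        assert list(pair.columns) == [0, 1, 3, 4]

    def test_single_row_gap_kept_as_indel_evidence(self):
        pair = induce_pair({"x": "AC-GT", "y": "AGAGT"}, "x", "y")
        assert pair.older == "AC-GT" and pair.younger == "AGAGT"

    def test_missing_row_rejected(self):
        with pytest.raises(ValueError):
            induce_pair({"x": "ACGT"}, "x", "zzz")


class TestClassifyMutations:
    def test_identical_sequences_all_zero(self):
        counts = classify_mutations(induce_pair({"a": "ACGT", "b": "ACGT"}, "a", "b"))
        assert all(v == 0 for v in counts.counts.values())

    def test_hand_enumerated_example(self):
        # A>G at position 1 (transition, AT>GC), T>A at 8 (transversion, AT>AT)
        pair = InducedPair("ACGTACGT", "GCGTACGA", np.arange(8))
        counts = classify_mutations(pair)
        assert counts.counts["transition"] == 1
        assert counts.counts["transversion"] == 1
        assert counts.counts["AT>GC"] == 1
        assert counts.counts["AT>AT"] == 1
        assert counts.counts["GC>AT"] == counts.counts["GC>GC"] == 0
        freqs = counts.frequencies
        for cls in ("transition", "transversion", "AT>GC", "AT>AT"):
            assert freqs[cls] == pytest.approx(12.5)

    def test_gap_run_counts_one_indel_event(self):
        pair = InducedPair("ACGTAA", "AC--AA", np.arange(6))
        counts = classify_mutations(pair)
        assert counts.counts["indel"] == 1
        assert counts.n_columns == 6 and counts.n_aligned == 4

    def test_n_columns_excluded_everywhere(self):
        pair = InducedPair("ANGT", "AAGT", np.arange(4))
        counts = classify_mutations(pair)
        assert counts.n_aligned == 3 and counts.n_columns == 3
        assert sum(counts.counts.values()) == 0

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACGT-"), st.sampled_from("ACGT-")
            ).filter(lambda p: p != ("-", "-")),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_class_identity_on_random_pairs(self, cols):
        """transition + transversion always equals the sum of the four
        GC-pressure classes (checked inside MutationCounts), and
        substitution counts equal a naive per-column recount."""
        older = "".join(c[0] for c in cols)
        younger = "".join(c[1] for c in cols)
        counts = classify_mutations(InducedPair(older, younger, np.arange(len(cols))))
        naive_subs = sum(
            1
            for o, y in cols
            if o != "-" and y != "-" and o != y
        )
        assert (
            counts.counts["transition"] + counts.counts["transversion"] == naive_subs
        )

    def test_truth_log_tallies_match_exactly(self):
        """Without indels, mutation counts between true ancestor and true
        descendant equal the simulator's event tallies."""
        from denovoscenario import SimConfig, simulate_catalogue

        config = SimConfig(
            n_loci_per_class={"S0+": 0, "S1": 0, "S2": 0, "intergene": 15},
            locus_length=300,
            flank_length=0,
            indel_rate=0.0,
            seed=2,
        )
        sim = simulate_catalogue(config)
        for truth in sim.truth.loci:
            a1 = truth.node_seqs["A1"]["core"]
            cer = truth.node_seqs["cerevisiae"]["core"]
            counts = classify_mutations(InducedPair(a1, cer, np.arange(len(a1))))
            events = truth.events["A1->cerevisiae"]["core"]
            n_ts = sum(
                1
                for e in events
                if e["kind"] == "sub"
                and {e["old"], e["new"]} in ({"A", "G"}, {"C", "T"})
            )
            n_subs = sum(1 for e in events if e["kind"] == "sub")
            assert counts.counts["transition"] == n_ts
            assert counts.counts["transversion"] == n_subs - n_ts


class TestGcContent:
    def test_genic_counts_third_codon_positions(self):
        assert gc_content("ATGGCGTAA", "genic_third_codon").value == pytest.approx(2 / 3)

    def test_nongenic_counts_whole_region(self):
        assert gc_content("ATGGCGTAA", "nongenic_whole").value == pytest.approx(4 / 9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_content("", "nongenic_whole")

    def test_genic_requires_codon_multiple(self):
        with pytest.raises(ValueError):
            gc_content("ACGTA", "genic_third_codon")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_whole_region_gc_strand_symmetric(self, seq):
        assert gc_content(seq, "nongenic_whole").value == pytest.approx(
            gc_content(revcomp(seq), "nongenic_whole").value
        )


class TestOrfScanning:
    def test_simple_orf(self):
        orfs = scan_orfs("ATGGCGTAA")
        assert len(orfs) == 1
        orf = orfs[0]
        assert (orf.start, orf.end, orf.frame, orf.length) == (1, 9, 0, 9)
        assert orf.has_stop

    def test_no_atg_no_orfs(self):
        assert scan_orfs("CCCCCCCCC") == []

    def test_kozak_rule_rejects_bad_context(self):
        # first in-frame ATG has T at -3; the second has A at -3
        assert locate_start("TTTATGAAAATGGC", RULE_KOZAK) == 10
        assert locate_start("TTTATGAAAATGGC", RULE_ATG) == 4

    def test_kozak_context_positions(self):
        assert locate_start("AAAATGGC", RULE_KOZAK) == 4
        assert locate_start("AAAATGGC", RULE_KOZAK_FULL) == 4  # +4 base is C
        assert locate_start("AAAATGGG", RULE_KOZAK_FULL) is None
        assert locate_start("CCCCCCCC", RULE_ATG) is None

    def test_context_may_reach_outside_segment(self):
        # segment starts at the ATG itself; -3 base lives in the context
        context = "AAAATGGCGTAA"
        pos = locate_start("ATGGCGTAA", RULE_KOZAK, context, segment_offset=3)
        assert pos == 1

    def test_kozak_full_match_implies_kozak_match(self):
        """A..ATG.C is strictly more specific than A..ATG at the same ATG."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(rng.choice(bases, size=30))
            orfs = scan_orfs(seq, RULE_ATG)
            for orf in orfs:
                if orf_start_has_kozak(seq, orf, RULE_KOZAK_FULL):
                    assert orf_start_has_kozak(seq, orf, RULE_KOZAK)


class TestAncestralOrfMapping:
    def test_identical_pair_maps_to_itself(self):
        seq = "TTTATGGCGAAATAATTT"
        pair = InducedPair(seq, seq, np.arange(len(seq)))
        recent = scan_orfs(seq, RULE_ATG)[0]
        anc = map_ancestral_orf(recent, pair, RULE_ATG)
        assert (anc.start, anc.end) == (recent.start, recent.end)

    def test_no_overlapping_candidate_returns_none(self):
        older = "CCCCCCCCCCCCCCCCCC"
        younger = "TTTATGGCGAAATAATTT"
        pair = InducedPair(older, younger, np.arange(len(older)))
        recent = scan_orfs(younger, RULE_ATG)[0]
        assert map_ancestral_orf(recent, pair, RULE_ATG) is None

    def test_frame_consistent_candidate_preferred(self):
        # ancestor has the same ORF shifted by a 3-nt indel: same frame
        older = "TTTATGGCGAAATAATTT"
        younger = "TTTGGGATGGCGAAATAATTT"
        rows = {"o": "---" + older, "y": younger}
        pair = induce_pair(rows, "o", "y")
        recent = scan_orfs(younger, RULE_ATG)[0]
        anc = map_ancestral_orf(recent, pair, RULE_ATG)
        assert anc is not None and anc.start == 4

    def test_overlap_selector_prefers_maximal_then_upstream(self):
        orfs = [
            OrfAnnotation(12, 26, 0, "ATG", 1, 27, True),
            OrfAnnotation(40, 60, 0, "ATG", 28, 60, True),
        ]
        assert select_overlapping_orf(orfs, (10, 30)).start == 12
        assert select_overlapping_orf(orfs, (61, 70)) is None


class TestChangeClassification:
    @pytest.mark.parametrize(
        "anc_len,recent_len,expected",
        [(90, 120, "Extend"), (120, 90, "Shrink"), (90, 90, "NoChange")],
    )
    def test_length_change_categories(self, anc_len, recent_len, expected):
        anc = OrfAnnotation(1, anc_len, 0, "ATG", 1, anc_len, True)
        rec = OrfAnnotation(1, recent_len, 0, "ATG", 1, recent_len, True)
        assert classify_length_change(anc, rec) == expected

    def test_missing_ancestor_excluded(self):
        rec = OrfAnnotation(1, 90, 0, "ATG", 1, 90, True)
        assert classify_length_change(None, rec) is None

    def test_rule_mismatch_rejected(self):
        anc = OrfAnnotation(1, 90, 0, "ATG", 1, 90, True)
        rec = OrfAnnotation(1, 90, 0, "A..ATG", 1, 90, True)
        with pytest.raises(ValueError):
            classify_length_change(anc, rec)

    @pytest.mark.parametrize(
        "anc_has,recent_has,expected",
        [
            (False, False, "No"),
            (True, True, "Retain"),
            (True, False, "Disappear"),
            (False, True, "Appear"),
        ],
    )
    def test_kozak_transitions_exhaustive(self, anc_has, recent_has, expected):
        assert classify_kozak_transition(anc_has, recent_has) == expected
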