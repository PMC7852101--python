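"""Routing, offsets, tailing, assignment, ncRNA filtering and count tables."""

import itertools

import pandas as pd
import pytest

from isomirkit.classifier import (
    DISCARD,
    EXACT_PATH,
    TAILING_PATH,
    VARIANT_PATH,
    ClassifierError,
    accumulate_counts,
    arm_proportions,
    assign_read,
    classify_reads,
    compute_offsets,
    detect_tailing,
    filter_ncrna,
    route_by_mismatch,
    summarize_types,
)
from isomirkit.identifier import OffsetSignature
from isomirkit.reference import GenomicInterval
from isomirkit.simulate import apply_offsets

from conftest import make_read


class TestComputeOffsets:
    MATURE_PLUS = GenomicInterval("c", 100, 121, "+")
    MATURE_MINUS = GenomicInterval("c", 100, 121, "-")

    def test_identity(self):
        read = GenomicInterval("c", 100, 121, "+")
        assert compute_offsets(read, self.MATURE_PLUS) == OffsetSignature()

    def test_plus_strand_one_shifted(self):
        # a read starting one nt after the canonical form, same length:
        # trimmed 1 at 5', extended 1 at 3' -> (1,0,0,1)
        read = GenomicInterval("c", 101, 122, "+")
        assert compute_offsets(read, self.MATURE_PLUS) == OffsetSignature(1, 0, 0, 1)

    def test_minus_strand_genomic_left_is_transcript_three_prime(self):
        read = GenomicInterval("c", 99, 120, "-")
        assert compute_offsets(read, self.MATURE_MINUS) == OffsetSignature(1, 0, 0, 1)

    def test_out_of_range_signals_none(self):
        read = GenomicInterval("c", 106, 127, "+")  # 5' shift of 6
        assert compute_offsets(read, self.MATURE_PLUS) is None

    def test_strand_mismatch_is_none(self):
        read = GenomicInterval("c", 100, 121, "-")
        assert compute_offsets(read, self.MATURE_PLUS) is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_offset_oracle_exhaustive(self, strand):
        """Reconstructing the read interval from mature + signature and
        re-measuring reproduces the signature, for all offsets 0-5 at both
        ends on both strands."""
        mature = GenomicInterval("c", 1000, 1021, strand)
        for m5, m3 in itertools.product(range(6), repeat=2):
            for d5, d3 in itertools.product([True, False], repeat=2):
                offs = OffsetSignature(
                    trim5=m5 if d5 else 0, ext5=0 if d5 else m5,
                    trim3=m3 if d3 else 0, ext3=0 if d3 else m3,
                )
                read = apply_offsets(mature, offs)
                assert compute_offsets(read, mature) == offs


class TestRouting:
    def test_exact_path(self, tiny_bundle):
        read = make_read(tiny_bundle, "chr1", 110, 131, "+")
        assert route_by_mismatch(read) == EXACT_PATH

    def test_single_internal_mismatch_is_variant_path(self, tiny_bundle):
        read = make_read(tiny_bundle, "chr1", 110, 131, "+")
        ref_base = read.sequence[9]
        alt = "A" if ref_base != "A" else "G"
        read = make_read(tiny_bundle, "chr1", 110, 131, "+", mutations={10: alt})
        assert len(read.mismatches) == 1
        assert route_by_mismatch(read) == VARIANT_PATH

    @pytest.mark.parametrize("n_tail", [1, 2, 3])
    def test_terminal_contiguous_mismatches_are_tailing_path(self, tiny_bundle, n_tail):
        muts = {}
        for pos in range(22 - n_tail + 1, 23):
            read0 = make_read(tiny_bundle, "chr1", 110, 131, "+")
            muts[pos] = "A" if read0.sequence[pos - 1] != "A" else "G"
        read = make_read(tiny_bundle, "chr1", 110, 131, "+", mutations=muts)
        assert route_by_mismatch(read) == TAILING_PATH

    def test_internal_plus_terminal_mismatch_is_discarded(self, tiny_bundle):
        read0 = make_read(tiny_bundle, "chr1", 110, 131, "+")
        muts = {
            5: "A" if read0.sequence[4] != "A" else "G",
            22: "A" if read0.sequence[21] != "A" else "G",
        }
        read = make_read(tiny_bundle, "chr1", 110, 131, "+", mutations=muts)
        assert route_by_mismatch(read) == DISCARD

    def test_too_many_mismatches_raise(self, tiny_bundle):
        read0 = make_read(tiny_bundle, "chr1", 110, 131, "+")
        muts = {
            p: "A" if read0.sequence[p - 1] != "A" else "G" for p in (3, 7, 12, 18)
        }
        read = make_read(tiny_bundle, "chr1", 110, 131, "+", mutations=muts)
        with pytest.raises(ClassifierError, match="maximum"):
            route_by_mismatch(read)


class TestDetectTailing:
    def test_plus_strand_tail_sequence_and_core(self, tiny_bundle):
        read0 = make_read(tiny_bundle, "chr1", 110, 131, "+")
        muts = {
            21: "A" if read0.sequence[20] != "A" else "G",
            22: "A" if read0.sequence[21] != "A" else "G",
        }
        read = make_read(tiny_bundle, "chr1", 110, 131, "+", mutations=muts)
        tail, core = detect_tailing(read)
        assert tail.present
        assert tail.tail_sequence == read.sequence_rna[-2:]
        assert (core.start, core.end) == (110, 129)

    def test_minus_strand_tail_comes_from_genomic_left(self, tiny_bundle):
        read0 = make_read(tiny_bundle, "chr2", 100, 121, "-")
        # transcript-terminal positions sit at the genomic-left end on -
        muts = {22: "A" if read0.sequence[21] != "A" else "G"}
        read = make_read(tiny_bundle, "chr2", 100, 121, "-", mutations=muts)
        assert read.mismatches[0].genomic_pos == 100
        tail, core = detect_tailing(read)
        assert tail.tail_sequence == read.sequence_rna[-1:]
        assert (core.start, core.end) == (101, 121)

    def test_exact_read_has_no_tail(self, tiny_bundle):
        read = make_read(tiny_bundle, "chr1", 110, 131, "+")
        tail, core = detect_tailing(read)
        assert not tail.present
        assert tail.tail_sequence == ""
        assert (core.start, core.end) == (110, 131)


class TestAssignment:
    def test_exact_match_assigns_with_zero_offsets(self, tiny_bundle):
        read = make_read(tiny_bundle, "chr1", 110, 131, "+")
        a = assign_read(read, tiny_bundle)
        assert a.status == "assigned"
        assert a.mature_id == "miR-a-5p"
        assert a.offsets == OffsetSignature()

    def test_shift_of_six_is_unassigned(self, tiny_bundle):
        read = make_read(tiny_bundle, "chr1", 116, 137, "+")
        assert assign_read(read, tiny_bundle).status == "unassigned"

    def test_multi_hit_in_two_precursors_is_ambiguous(self, tiny_bundle):
        hit1 = make_read(tiny_bundle, "chr1", 110, 131, "+", read_id="r")
        hit2 = make_read(tiny_bundle, "chr2", 100, 121, "-", read_id="r")
        for hit in (hit1, hit2):
            hit.num_hits = 2
        a = assign_read([hit1, hit2], tiny_bundle)
        assert a.status == "ambiguous"
        assert set(a.candidates) == {"miR-a-5p", "miR-b-5p"}

    def test_hit_outside_any_precursor_loses_to_in_precursor_hit(self, tiny_bundle):
        hit1 = make_read(tiny_bundle, "chr1", 110, 131, "+", read_id="r")
        hit2 = make_read(tiny_bundle, "chr1", 300, 321, "+", read_id="r")
        a = assign_read([hit1, hit2], tiny_bundle)
        assert a.status == "assigned"
        assert a.mature_id == "miR-a-5p"

    def test_raising_max_shift_never_decreases_assignments(self, small_sim):
        cfg, bundle, reads, truth = small_sim
        counts = []
        for shift in range(0, 6):
            calls = classify_reads(reads, bundle, max_shift=shift)
            counts.append(sum(c.status == "assigned" for c in calls))
        assert counts == sorted(counts)


class TestNcRnaFilter:
    def test_rrna_reads_removed_and_counted(self, tiny_bundle):
        reads = [
            make_read(tiny_bundle, "chr1", 310, 331, "+", read_id=f"rr{i}")
            for i in range(3)
        ] + [
            make_read(tiny_bundle, "chr1", 110, 131, "+", read_id=f"mi{i}")
            for i in range(5)
        ] + [
            make_read(tiny_bundle, "chr2", 200, 221, "+", read_id=f"ln{i}")
            for i in range(2)
        ]
        retained, counts = filter_ncrna(reads, tiny_bundle)
        assert len(retained) == 7
        assert counts == {"rRNA": 3, "miRNA": 5, "lncRNA": 2}

    def test_unannotated_read_is_retained(self, tiny_bundle):
        reads = [make_read(tiny_bundle, "chr1", 10, 31, "+")]
        retained, counts = filter_ncrna(reads, tiny_bundle)
        assert len(retained) == 1
        assert counts == {"unannotated": 1}

    def test_class_counts_partition_the_input(self, small_sim):
        cfg, bundle, reads, truth = small_sim
        retained, counts = filter_ncrna(reads, bundle)
        assert sum(counts.values()) == len(reads)


class TestReadConservation:
    def test_statuses_partition_reads(self, small_sim):
        cfg, bundle, reads, truth = small_sim
        calls = classify_reads(reads, bundle)
        tallies = {"assigned": 0, "ambiguous": 0, "unassigned": 0, "discarded": 0}
        for c in calls:
            tallies[c.status] += 1
        assert sum(tallies.values()) == len({r.read_id for r in reads})


def _call(status="assigned", mature="miR-a-5p", seq="ACGUACGUACGUACGUACGUAC",
          offsets=OffsetSignature(), candidates=()):
    from isomirkit.classifier import IsomiRCall

    return IsomiRCall(
        "r", status, mature_id=mature if status == "assigned" else None,
        offsets=offsets if status == "assigned" else None,
        sequence=seq, candidates=candidates,
    )


class TestCounts:
    COND = {"s1": "condition1", "s2": "condition2"}

    def test_totals_split_by_status(self):
        calls = {
            "s1": [_call() for _ in range(90)]
            + [_call(status="ambiguous", candidates=("a", "b")) for _ in range(6)]
            + [_call(status="unassigned") for _ in range(4)],
            "s2": [],
        }
        unamb, amb = accumulate_counts(calls, self.COND)
        assert int(unamb["s1"].sum()) == 90
        assert int(amb["s1"].sum()) == 6
        assert int(unamb["s2"].sum()) == 0  # empty sample -> zero column

    def test_shared_isomir_occupies_one_row(self):
        calls = {"s1": [_call()], "s2": [_call(), _call()]}
        unamb, _ = accumulate_counts(calls, self.COND)
        assert unamb.shape[0] == 1
        assert list(unamb.iloc[0]) == [1, 2]

    def test_unknown_sample_rejected(self):
        with pytest.raises(ClassifierError, match="condition map"):
            accumulate_counts({"sX": []}, self.COND)


class TestSummaries:
    COND = {"s1": "condition1", "s2": "condition2"}

    def _matrix(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2"]).rename_axis("isomiR_ID")

    def test_all_canonical_is_proportion_one(self):
        m = pd.DataFrame({"s1": [5], "s2": [3]}, index=["ACGU_m1_0_0_0_0_NA_0_NA_F_NA"])
        out = summarize_types(m, self.COND)
        assert out.loc["canonical", "condition1"] == 1.0

    def test_constructed_split(self):
        m = pd.DataFrame(
            {"s1": [546, 454], "s2": [0, 1]},
            index=[
                "ACGU_m1_0_0_1_0_NA_0_NA_F_NA",  # 3' trimming
                "ACGU_m2_0_0_0_0_NA_0_NA_F_NA",  # canonical
            ],
        )
        out = summarize_types(m, self.COND)
        assert out.loc["3p_trim", "condition1"] == pytest.approx(0.546)
        assert out.loc["canonical", "condition1"] == pytest.approx(0.454)

    def test_proportions_sum_to_one_and_scale_invariant(self):
        m = pd.DataFrame(
            {"s1": [10, 20, 5], "s2": [1, 2, 3]},
            index=[
                "ACGU_m1_0_0_0_0_NA_0_NA_F_NA",
                "ACGU_m1_1_0_0_1_NA_0_NA_F_NA",
                "ACGU_m1_0_0_0_0_NA_0_NA_T_UU",
            ],
        )
        out = summarize_types(m, self.COND)
        assert out["condition1"].sum() == pytest.approx(1.0, abs=1e-9)
        scaled = summarize_types(m * 10, self.COND)
        pd.testing.assert_frame_equal(out, scaled)

    def test_all_zero_matrix_is_an_error(self):
        m = pd.DataFrame({"s1": [0], "s2": [0]}, index=["ACGU_m1_0_0_0_0_NA_0_NA_F_NA"])
        with pytest.raises(ClassifierError):
            summarize_types(m, self.COND)


class TestArmProportions:
    COND = {"s1": "condition1", "s2": "condition2"}

    def test_all_5p(self, tiny_bundle):
        m = pd.DataFrame(
            {"s1": [4], "s2": [1]}, index=["ACGU_miR-a-5p_0_0_0_0_NA_0_NA_F_NA"]
        )
        out = arm_proportions(m, tiny_bundle, self.COND)
        assert out.loc["5p", "condition1"] == 1.0
        assert out.loc["3p", "condition1"] == 0.0

    def test_three_to_one_split_and_row_merge_invariance(self, tiny_bundle):
        m = pd.DataFrame(
            {"s1": [2, 1, 1], "s2": [0, 0, 0]},
            index=[
                "ACGU_miR-a-5p_0_0_0_0_NA_0_NA_F_NA",
                "ACGA_miR-a-5p_1_0_0_1_NA_0_NA_F_NA",
                "ACGC_miR-a-3p_0_0_0_0_NA_0_NA_F_NA",
            ],
        )
        out = arm_proportions(m, tiny_bundle, self.COND)
        assert out.loc["5p", "condition1"] == pytest.approx(0.75)
        merged = pd.DataFrame(
            {"s1": [3, 1], "s2": [0, 0]},
            index=[
                "ACGU_miR-a-5p_0_0_0_0_NA_0_NA_F_NA",
                "ACGC_miR-a-3p_0_0_0_0_NA_0_NA_F_NA",
            ],
        )
        out2 = arm_proportions(merged, tiny_bundle, self.COND)
        assert out.loc["5p", "condition1"] == out2.loc["5p", "condition1"]

    def test_unresolvable_mature_is_an_error(self, tiny_bundle):
        m = pd.DataFrame({"s1": [1], "s2": [0]}, index=["ACGU_miR-zz_0_0_0_0_NA_0_NA_F_NA"])
        with pytest.raises(ClassifierError, match="miR-zz"):
            arm_proportions(m, tiny_bundle, self.COND)
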