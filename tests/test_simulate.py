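"""Simulator determinism, injection properties, coverage and scoring."""

import dataclasses

import pytest

from isomirkit.classifier import IsomiRCall, classify_reads
from isomirkit.identifier import OffsetSignature
from isomirkit.reference import GenomicInterval
from isomirkit.simulate import (
    PerfMetrics,
    SimConfig,
    SimConfigError,
    TruthRecord,
    apply_offsets,
    inject_variants_and_tails,
    mean_hairpin_coverage,
    mean_mature_coverage,
    read_truth_tsv,
    score_performance,
    simulate_reads,
    simulate_reference,
    write_reference,
    write_truth_tsv,
)


class TestSimulateReference:
    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        cfg = SimConfig(n_precursors=5, rng_seed=1)
        for run in ("one", "two"):
            b = simulate_reference(cfg)
            write_reference(b, str(tmp_path / f"{run}.fa"), str(tmp_path / f"{run}.gff3"))
        assert (tmp_path / "one.fa").read_bytes() == (tmp_path / "two.fa").read_bytes()
        assert (tmp_path / "one.gff3").read_bytes() == (tmp_path / "two.gff3").read_bytes()

    def test_zero_precursors_is_empty_but_valid(self):
        b = simulate_reference(SimConfig(n_precursors=0))
        assert b.precursors == {}
        assert b.matures == {}

    @pytest.mark.parametrize("seed", range(12))
    def test_generated_bundles_pass_reference_validation(self, seed):
        # ReferenceBundle.__init__ runs full validation; varied geometry
        cfg = SimConfig(
            n_precursors=1 + seed % 4,
            mature_length=22 if seed % 2 == 0 else 16,
            rng_seed=seed,
        )
        b = simulate_reference(cfg)
        assert len(b.matures) == 2 * len(b.precursors)
        for mat in b.matures.values():
            prec = b.precursors[mat.precursor_id]
            assert prec.interval.contains(mat.interval)
            assert len(mat.sequence) == cfg.mature_length

    def test_mature_too_long_for_hairpin_is_config_error(self):
        with pytest.raises(SimConfigError, match="mature_length"):
            SimConfig(precursor_length=70, mature_length=35)

    def test_exclusive_fractions_cannot_exceed_one(self):
        with pytest.raises(SimConfigError, match="exceeds 1"):
            SimConfig(snv_fraction=0.7, tail_fraction=0.6)

    def test_round_trip_through_files(self, tmp_path):
        from isomirkit.reference import load_reference

        cfg = SimConfig(n_precursors=3, rng_seed=9)
        b = simulate_reference(cfg)
        write_reference(b, str(tmp_path / "g.fa"), str(tmp_path / "m.gff3"))
        loaded = load_reference(str(tmp_path / "g.fa"), str(tmp_path / "m.gff3"))
        assert set(loaded.matures) == set(b.matures)
        for mid, mat in b.matures.items():
            assert loaded.matures[mid].sequence == mat.sequence
            assert loaded.matures[mid].arm == mat.arm


class TestSimulateReads:
    def test_zero_depth_zero_reads(self):
        cfg = SimConfig(n_precursors=2, mature_depth=0, hairpin_depth=0, rng_seed=1)
        b = simulate_reference(cfg)
        reads, truth = simulate_reads(b, cfg)
        assert reads == [] and truth == {}

    def test_every_truth_record_reconstructs_its_interval(self, small_sim):
        cfg, bundle, reads, truth = small_sim
        for read in reads:
            rec = truth[read.read_id]
            if rec.mature_id is None:
                continue
            mature = bundle.matures[rec.mature_id]
            core = apply_offsets(mature.interval, rec.offsets)
            tail_n = len(rec.tail_seq or "")
            if read.strand == "+":
                assert (read.start, read.end - tail_n) == (core.start, core.end)
            else:
                assert (read.start + tail_n, read.end) == (core.start, core.end)

    def test_mean_mature_coverage_near_target(self, small_sim):
        cfg, bundle, reads, truth = small_sim
        cov = mean_mature_coverage(reads, truth, bundle)
        assert cov == pytest.approx(cfg.mature_depth, rel=0.05)

    def test_mean_hairpin_coverage_near_target(self, small_sim):
        cfg, bundle, reads, truth = small_sim
        cov = mean_hairpin_coverage(reads, truth, bundle)
        assert cov == pytest.approx(cfg.hairpin_depth, rel=0.15)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_precursors=1, mature_depth=50, hairpin_depth=10, rng_seed=4)
        b = simulate_reference(cfg)
        r1, t1 = simulate_reads(b, cfg)
        r2, t2 = simulate_reads(b, cfg)
        assert r1 == r2 and t1 == t2


class TestInjection:
    def test_zero_fractions_leave_reads_unchanged(self):
        cfg = SimConfig(
            n_precursors=1, mature_depth=50, hairpin_depth=0,
            snv_fraction=0.0, tail_fraction=0.0, rng_seed=3,
        )
        b = simulate_reference(cfg)
        reads, truth = simulate_reads(b, cfg)
        mutated, truth2 = inject_variants_and_tails(reads, truth, cfg, b)
        assert mutated == reads
        assert truth2 == truth

    def test_snv_fraction_one_marks_every_mature_read(self):
        cfg = SimConfig(
            n_precursors=1, mature_depth=80, hairpin_depth=0,
            snv_fraction=1.0, tail_fraction=0.0, rng_seed=3,
        )
        b = simulate_reference(cfg)
        reads, truth = simulate_reads(b, cfg)
        mutated, truth2 = inject_variants_and_tails(reads, truth, cfg, b)
        for read in mutated:
            rec = truth2[read.read_id]
            assert rec.variant is not None
            pos, ref, alt = rec.variant
            assert alt != ref
            assert read.sequence[pos - 1] == alt
            assert 2 <= pos <= len(read) - 1  # non-terminal

    def test_tail_bases_are_untemplated(self):
        cfg = SimConfig(
            n_precursors=2, mature_depth=60, hairpin_depth=0,
            snv_fraction=0.0, tail_fraction=1.0, rng_seed=6,
        )
        b = simulate_reference(cfg)
        reads, truth = simulate_reads(b, cfg)
        mutated, truth2 = inject_variants_and_tails(reads, truth, cfg, b)
        for read in mutated:
            rec = truth2[read.read_id]
            assert rec.tail_seq and 1 <= len(rec.tail_seq) <= 3
            # every tail base must differ from the templated genome base
            for mm in read.mismatches:
                assert mm.read_base != mm.ref_base


class TestScoring:
    def _truth(self):
        return {
            "r1": TruthRecord("A", OffsetSignature()),
            "r2": TruthRecord("A", OffsetSignature()),
            "r3": TruthRecord("B", OffsetSignature()),
        }

    def _call(self, rid, mature=None, status="assigned"):
        return IsomiRCall(
            rid, status, mature_id=mature,
            offsets=OffsetSignature() if status == "assigned" else None,
        )

    def test_all_correct_is_perfect(self):
        calls = [self._call("r1", "A"), self._call("r2", "A"), self._call("r3", "B")]
        m = score_performance(self._truth(), calls)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.type_accuracy == 1.0

    def test_mixed_outcome_matches_hand_computation(self):
        # one correct, one misassigned, one unassigned:
        # TP=1, FP=1, FN=1 -> sensitivity 1/2, specificity 1/2
        calls = [
            self._call("r1", "A"),
            self._call("r2", "B"),
            self._call("r3", status="unassigned"),
        ]
        m = score_performance(self._truth(), calls)
        assert (m.tp, m.fp, m.fn) == (1, 1, 1)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == pytest.approx(0.5)

    def test_unknown_read_id_is_an_error(self):
        with pytest.raises(SimConfigError, match="rX"):
            score_performance(self._truth(), [self._call("rX", "A")])

    def test_empty_denominators_are_none_not_zero_division(self):
        m = PerfMetrics(tp=0, fp=0, fn=0, type_accuracy=float("nan"))
        assert m.sensitivity is None and m.specificity is None

    def test_small_full_run_reaches_perfect_accuracy(self, small_sim):
        cfg, bundle, reads, truth = small_sim
        calls = classify_reads(reads, bundle)
        m = score_performance(truth, calls)
        assert m.fp == 0 and m.fn == 0
        assert m.type_accuracy == 1.0

    def test_sixteen_nt_run_completes_and_reports(self):
        cfg = SimConfig(
            n_precursors=2, mature_length=16, mature_depth=400,
            hairpin_depth=50, rng_seed=8,
        )
        b = simulate_reference(cfg)
        reads, truth = simulate_reads(b, cfg)
        reads, truth = inject_variants_and_tails(reads, truth, cfg, b)
        calls = classify_reads(reads, b)
        m = score_performance(truth, calls)
        assert m.sensitivity is not None and m.specificity is not None
        assert 0.0 <= m.type_accuracy <= 1.0


class TestParameterRecovery:
    def test_injected_snvs_recovered_across_twenty_seeds(self):
        """Across 20 seeds, every confirmed variant call recovers the injected
        position and alleles; reads meeting the depth/alt thresholds are
        recovered at 100%."""
        for seed in range(20):
            cfg = SimConfig(
                n_precursors=1, mature_depth=400, hairpin_depth=0,
                snv_fraction=0.5, tail_fraction=0.3, rng_seed=seed,
            )
            b = simulate_reference(cfg)
            reads, truth = simulate_reads(b, cfg)
            reads, truth = inject_variants_and_tails(reads, truth, cfg, b)
            calls = classify_reads(reads, b)
            for call in calls:
                rec = truth[call.read_id]
                if rec.variant is not None and call.variant is not None:
                    pos, ref, alt = rec.variant
                    assert call.variant.position == pos
                    assert call.variant.ref_base == ref
                    assert call.variant.alt_base == alt
                if rec.tail_seq:
                    assert call.tail.tail_sequence == rec.tail_seq


def test_truth_tsv_round_trip(tmp_path, small_sim):
    cfg, bundle, reads, truth = small_sim
    path = tmp_path / "truth.tsv"
    write_truth_tsv(truth, str(path))
    loaded = read_truth_tsv(str(path))
    assert loaded == truth
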