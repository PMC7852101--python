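"""Ground-truth small-RNA-seq simulation and classifier benchmarking.

The simulator builds a synthetic reference — hairpin precursors of ~70 nt,
each carrying a 5p and a 3p mature of 22 nt (or 16 nt) — and synthesizes
reads placed at their true genomic coordinates (the *correctly mapped*
regime, which isolates the classifier from aligner error).  Mature-derived
reads carry 0-5 nt end offsets; a configurable fraction then receive one
internal single-nucleotide substitution, and a disjoint fraction receive a
1-3 nt untemplated 3' tail.  Hairpin-background reads are drawn from start
positions that do not satisfy the +/-5 nt both-end rule for either mature,
so their correct classification is "unassigned".  Read counts are calibrated
so the expected mean per-base coverage is ``mature_depth`` over mature
regions and ``hairpin_depth`` over the non-mature hairpin background.

Every read has exactly one truth record; :func:`score_performance` compares
classifier calls against truth using the benchmark definitions: a read
assigned to its miRNA of origin is a true positive, one assigned elsewhere a
false positive, one left unassigned a false negative, with sensitivity
TP/(TP+FN) and specificity TP/(TP+FP) (the latter coincides with precision).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .classifier import IsomiRCall
from .identifier import OffsetSignature
from .reference import (
    GenomicInterval,
    KnownVariantStore,
    MatureRecord,
    NcRnaFeature,
    PrecursorRecord,
    ReferenceBundle,
    dna_to_rna,
    rna_to_dna,
)
from .samio import AlignedRead, Mismatch

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulation benchmark.

    Depths follow the benchmark protocol (1000x over hairpins, 10,000x over
    mature-derived transcripts); offsets are drawn per end from
    ``offset_distribution`` over magnitudes 0-5 (uniform by default), with
    trimming and extension equiprobable for non-zero magnitudes.
    """

    n_precursors: int = 5
    precursor_length: int = 70
    mature_length: int = 22
    hairpin_depth: float = 1000.0
    mature_depth: float = 10000.0
    snv_fraction: float = 0.10
    tail_fraction: float = 0.10
    tail_length_range: tuple[int, int] = (1, 3)
    offset_distribution: tuple[float, ...] = (1 / 6,) * 6
    max_shift: int = 5
    seq_error_rate: float = 0.0
    spacer_length: int = 50
    end_margin: int = 9  # nt between precursor ends and mature ends
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_precursors < 0:
            raise SimConfigError("n_precursors must be >= 0")
        if self.hairpin_depth < 0 or self.mature_depth < 0:
            raise SimConfigError("depths must be >= 0")
        for name in ("snv_fraction", "tail_fraction", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1]")
        if self.snv_fraction + self.tail_fraction > 1.0:
            raise SimConfigError(
                "snv_fraction + tail_fraction exceeds 1 (groups are exclusive)"
            )
        if 2 * self.mature_length + 2 * self.end_margin + 2 > self.precursor_length:
            raise SimConfigError(
                "mature_length too long for precursor_length: the two matures "
                "and the loop do not fit the hairpin"
            )
        lo, hi = self.tail_length_range
        if not (1 <= lo <= hi <= 3):
            raise SimConfigError("tail_length_range must lie within 1..3")
        if abs(sum(self.offset_distribution) - 1.0) > 1e-9 or len(self.offset_distribution) != 6:
            raise SimConfigError("offset_distribution must be 6 probabilities summing to 1")


@dataclass
class TruthRecord:
    """What one simulated read really is."""

    mature_id: str | None  # None for hairpin-background reads
    offsets: OffsetSignature | None = None
    variant: tuple[int, str, str] | None = None  # (read pos, ref, alt), transcript DNA
    tail_seq: str | None = None  # RNA


#: mapping of read id -> its ground-truth record
SimTruth = dict[str, TruthRecord]


@dataclass
class PerfMetrics:
    tp: int
    fp: int
    fn: int
    type_accuracy: float
    per_type: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None


# ---------------------------------------------------------------------------
# reference synthesis


def apply_offsets(mature: GenomicInterval, offsets: OffsetSignature) -> GenomicInterval:
    """Genomic interval of a read with the given end offsets (inverse of
    offset computation)."""
    if mature.strand == "+":
        start = mature.start + offsets.trim5 - offsets.ext5
        end = mature.end + offsets.ext3 - offsets.trim3
    else:
        end = mature.end - offsets.trim5 + offsets.ext5
        start = mature.start - offsets.ext3 + offsets.trim3
    return GenomicInterval(mature.chrom, start, end, mature.strand)


def simulate_reference(config: SimConfig) -> ReferenceBundle:
    """Synthesize hairpin precursors with embedded 5p/3p matures.

    Precursors alternate between the + and - strand on a single chromosome,
    separated by spacers; a miRNA-biotype ncRNA feature mirrors each
    precursor so class counting works out of the box.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 101]))
    chrom = "chrS"
    P, L, m = config.precursor_length, config.mature_length, config.end_margin
    pieces: list[str] = []
    cursor = 0
    precursors: dict[str, PrecursorRecord] = {}
    matures: dict[str, MatureRecord] = {}
    ncrna: list[NcRnaFeature] = []

    def _rand_seq(n: int) -> str:
        return "".join(rng.choice(list(_BASES), size=n))

    for i in range(config.n_precursors):
        pieces.append(_rand_seq(config.spacer_length))
        cursor += config.spacer_length
        strand = "+" if i % 2 == 0 else "-"
        pstart = cursor + 1
        pieces.append(_rand_seq(P))
        cursor += P
        pend = cursor
        iv = GenomicInterval(chrom, pstart, pend, strand)
        name = f"sim-mir-{i + 1}"
        # transcript coordinates of the matures within the precursor
        t5 = (m + 1, m + L)
        t3 = (P - m - L + 1, P - m)
        mat_ivs = {}
        for arm, (ts, te) in (("5p", t5), ("3p", t3)):
            if strand == "+":
                g = GenomicInterval(chrom, pstart + ts - 1, pstart + te - 1, strand)
            else:
                g = GenomicInterval(chrom, pstart + P - te, pstart + P - ts, strand)
            mat_ivs[arm] = g
        precursors[name] = PrecursorRecord(id=name, interval=iv, sequence="")
        for arm in ("5p", "3p"):
            mid = f"sim-miR-{i + 1}-{arm}"
            matures[mid] = MatureRecord(
                id=mid, precursor_id=name, interval=mat_ivs[arm], arm=arm, sequence=""
            )
            precursors[name].matures.append(mid)
        ncrna.append(NcRnaFeature(id=f"{name}-feat", biotype="miRNA", interval=iv))
    pieces.append(_rand_seq(config.spacer_length))
    genome = {chrom: "".join(pieces)}

    for prec in precursors.values():
        raw = genome[chrom][prec.interval.start - 1 : prec.interval.end]
        if prec.interval.strand == "-":
            raw = "".join(_COMPLEMENT[b] for b in reversed(raw))
        prec.sequence = dna_to_rna(raw)
    for mat in matures.values():
        raw = genome[chrom][mat.interval.start - 1 : mat.interval.end]
        if mat.interval.strand == "-":
            raw = "".join(_COMPLEMENT[b] for b in reversed(raw))
        mat.sequence = dna_to_rna(raw)
    return ReferenceBundle(
        genome=genome,
        precursors=precursors,
        matures=matures,
        ncrna=ncrna,
        known_variants=KnownVariantStore(),
        taxon_mode="animal",
    )


def write_reference(bundle: ReferenceBundle, fasta_path: str, gff_path: str) -> None:
    """Write the bundle's genome and miRNA annotation to FASTA/GFF3 files."""
    with open(fasta_path, "w") as fa:
        for chrom in sorted(bundle.genome):
            fa.write(f">{chrom}\n")
            seq = str(bundle.genome[chrom])
            for i in range(0, len(seq), 60):
                fa.write(seq[i : i + 60] + "\n")
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for pid in sorted(bundle.precursors):
            prec = bundle.precursors[pid]
            iv = prec.interval
            gff.write(
                f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID=MI-{pid};Name={pid}\n"
            )
            for mat in (bundle.matures[m] for m in prec.matures):
                mv = mat.interval
                gff.write(
                    f"{mv.chrom}\t.\tmiRNA\t{mv.start}\t{mv.end}\t.\t{mv.strand}\t.\t"
                    f"ID=MIMAT-{mat.id};Name={mat.id};Derives_from=MI-{pid}\n"
                )


# ---------------------------------------------------------------------------
# read synthesis


def _expected_trim_per_end(dist: tuple[float, ...]) -> float:
    return 0.5 * sum(k * p for k, p in enumerate(dist))


def _draw_offsets(rng: np.random.Generator, config: SimConfig) -> OffsetSignature:
    mags = rng.choice(6, size=2, p=config.offset_distribution)
    dirs = rng.random(2) < 0.5  # True => trim
    t5 = int(mags[0]) if (mags[0] and dirs[0]) else 0
    e5 = int(mags[0]) if (mags[0] and not dirs[0]) else 0
    t3 = int(mags[1]) if (mags[1] and dirs[1]) else 0
    e3 = int(mags[1]) if (mags[1] and not dirs[1]) else 0
    return OffsetSignature(t5, e5, t3, e3)


def simulate_reads(
    bundle: ReferenceBundle, config: SimConfig
) -> tuple[list[AlignedRead], dict[str, TruthRecord]]:
    """Synthesize templated reads at their true coordinates, with truth.

    Mature-derived reads carry end offsets drawn from the configured
    distribution; the per-mature read count is calibrated so the expected
    mean per-base coverage over the mature equals ``mature_depth``.
    Hairpin-background reads are uniform over start positions outside the
    +/-``max_shift`` windows of both matures.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 202]))
    reads: list[AlignedRead] = []
    truth: dict[str, TruthRecord] = {}
    L = config.mature_length
    P = config.precursor_length
    counter = 0

    exp_overlap = L - 2.0 * _expected_trim_per_end(config.offset_distribution)
    n_per_mature = int(round(config.mature_depth * L / exp_overlap)) if config.mature_depth else 0

    for pid in sorted(bundle.precursors):
        prec = bundle.precursors[pid]
        mats = bundle.matures_of(pid)
        # -- mature-derived reads
        for mat in sorted(mats, key=lambda m: m.id):
            for _ in range(n_per_mature):
                offs = _draw_offsets(rng, config)
                iv = apply_offsets(mat.interval, offs)
                seq = rna_to_dna(bundle.extract_sequence(iv))
                counter += 1
                rid = f"simr{counter:07d}"
                reads.append(
                    AlignedRead(
                        read_id=rid, chrom=iv.chrom, start=iv.start, end=iv.end,
                        strand=iv.strand, sequence=seq, quals=[40] * len(seq),
                        mapping_quality=42,
                    )
                )
                truth[rid] = TruthRecord(mature_id=mat.id, offsets=offs)
        # -- hairpin-background reads
        if config.hairpin_depth > 0:
            mature_t_starts = []
            for mat in mats:
                if prec.interval.strand == "+":
                    ts = mat.interval.start - prec.interval.start + 1
                else:
                    ts = prec.interval.end - mat.interval.end + 1
                mature_t_starts.append(ts)
            allowed = [
                s
                for s in range(1, P - L + 2)
                if all(abs(s - ts) > config.max_shift for ts in mature_t_starts)
            ]
            if allowed:
                mature_mask = np.zeros(P + 1, dtype=bool)
                for mat, ts in zip(mats, mature_t_starts):
                    mature_mask[ts : ts + len(mat.interval)] = True
                w = np.zeros(P + 1, dtype=float)
                for s in allowed:
                    w[s : s + L] += 1.0
                bg_positions = ~mature_mask
                bg_positions[0] = False
                mean_w = float(w[bg_positions].mean())
                n_h = int(round(config.hairpin_depth * len(allowed) / mean_w)) if mean_w else 0
                starts = rng.choice(allowed, size=n_h)
                for s in starts:
                    s = int(s)
                    if prec.interval.strand == "+":
                        iv = GenomicInterval(
                            prec.interval.chrom,
                            prec.interval.start + s - 1,
                            prec.interval.start + s + L - 2,
                            "+",
                        )
                    else:
                        iv = GenomicInterval(
                            prec.interval.chrom,
                            prec.interval.end - s - L + 2,
                            prec.interval.end - s + 1,
                            "-",
                        )
                    seq = rna_to_dna(bundle.extract_sequence(iv))
                    counter += 1
                    rid = f"simr{counter:07d}"
                    reads.append(
                        AlignedRead(
                            read_id=rid, chrom=iv.chrom, start=iv.start, end=iv.end,
                            strand=iv.strand, sequence=seq, quals=[40] * len(seq),
                            mapping_quality=42,
                        )
                    )
                    truth[rid] = TruthRecord(mature_id=None)
    return reads, truth


def inject_variants_and_tails(
    reads: list[AlignedRead],
    truth: dict[str, TruthRecord],
    config: SimConfig,
    bundle: ReferenceBundle,
) -> tuple[list[AlignedRead], dict[str, TruthRecord]]:
    """Inject internal SNVs and untemplated 3' tails into disjoint read groups.

    ``snv_fraction`` of mature-derived reads receive one substitution at a
    uniform random non-terminal position; ``tail_fraction`` receive a 1-3 nt
    3' tail whose bases are resampled until untemplated (different from the
    downstream genomic base).  Returns mutated copies; inputs are untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 303]))
    out_reads: list[AlignedRead] = []
    out_truth: dict[str, TruthRecord] = {}
    for read in reads:
        rec = truth[read.read_id]
        read = dataclasses.replace(read, quals=list(read.quals), mismatches=list(read.mismatches))
        rec = dataclasses.replace(rec)
        if rec.mature_id is not None:
            u = rng.random()
            if u < config.snv_fraction:
                _inject_snv(read, rec, rng, bundle.matures[rec.mature_id].interval)
            elif u < config.snv_fraction + config.tail_fraction:
                _inject_tail(read, rec, rng, config, bundle)
        if config.seq_error_rate > 0:
            _inject_errors(read, rng, config.seq_error_rate, bundle)
        out_reads.append(read)
        out_truth[read.read_id] = rec
    return out_reads, out_truth


def _inject_snv(
    read: AlignedRead,
    rec: TruthRecord,
    rng: np.random.Generator,
    mature_iv: GenomicInterval,
) -> None:
    length = len(read)
    # non-terminal read positions (2..length-1) strictly inside the mature
    # body: interior sites carry the full mature read depth, and every
    # covering offset read can contribute alternate support (the adequate-
    # depth regime); the outermost mature positions are reachable
    # non-terminally only by rare extension reads
    eligible = [
        p
        for p in range(2, length)
        if mature_iv.start < read.genomic_pos(p) < mature_iv.end
    ]
    pos = int(eligible[int(rng.integers(len(eligible)))]) if eligible else int(
        rng.integers(2, length)
    )
    ref = read.sequence[pos - 1]
    alt = [b for b in _BASES if b != ref][int(rng.integers(3))]
    read.sequence = read.sequence[: pos - 1] + alt + read.sequence[pos:]
    read.mismatches.append(Mismatch(pos, read.genomic_pos(pos), ref, alt, 40))
    rec.variant = (pos, ref, alt)


def _inject_tail(
    read: AlignedRead,
    rec: TruthRecord,
    rng: np.random.Generator,
    config: SimConfig,
    bundle: ReferenceBundle,
) -> None:
    lo, hi = config.tail_length_range
    k = int(rng.integers(lo, hi + 1))
    tail = []
    for j in range(1, k + 1):
        if read.strand == "+":
            gpos = read.end + j
            templ = bundle.fetch(read.chrom, gpos, gpos)
        else:
            gpos = read.start - j
            templ = _COMPLEMENT[bundle.fetch(read.chrom, gpos, gpos)]
        base = _BASES[int(rng.integers(4))]
        while base == templ:  # untemplated by construction
            base = _BASES[int(rng.integers(4))]
        tail.append((gpos, templ, base))
    length = len(read)
    read.sequence = read.sequence + "".join(b for _, _, b in tail)
    read.quals.extend([40] * k)
    if read.strand == "+":
        read.end += k
    else:
        read.start -= k
    for j, (gpos, templ, base) in enumerate(tail, start=1):
        read.mismatches.append(Mismatch(length + j, gpos, templ, base, 40))
    rec.tail_seq = dna_to_rna("".join(b for _, _, b in tail))


def _inject_errors(
    read: AlignedRead, rng: np.random.Generator, rate: float, bundle: ReferenceBundle
) -> None:
    from .samio import compute_mismatches

    seq = list(read.sequence)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alt = _BASES[int(rng.integers(4))]
        while alt == seq[i]:
            alt = _BASES[int(rng.integers(4))]
        seq[i] = alt
    if len(hits):
        read.sequence = "".join(seq)
        read.mismatches = compute_mismatches(read, bundle)


# ---------------------------------------------------------------------------
# coverage measurement and scoring


def mean_mature_coverage(
    reads: list[AlignedRead], truth: dict[str, TruthRecord], bundle: ReferenceBundle
) -> float:
    """Mean per-base depth over mature regions from mature-derived reads."""
    return _mean_coverage(
        [r for r in reads if truth[r.read_id].mature_id is not None],
        [m.interval for m in bundle.matures.values()],
    )


def mean_hairpin_coverage(
    reads: list[AlignedRead], truth: dict[str, TruthRecord], bundle: ReferenceBundle
) -> float:
    """Mean per-base depth over non-mature hairpin positions from background reads."""
    mature_pos = set()
    for m in bundle.matures.values():
        mature_pos.update(range(m.interval.start, m.interval.end + 1))
    targets = []
    for p in bundle.precursors.values():
        run: list[int] = []
        for pos in range(p.interval.start, p.interval.end + 1):
            if pos in mature_pos:
                if run:
                    targets.append(
                        GenomicInterval(p.interval.chrom, run[0], run[-1], p.interval.strand)
                    )
                    run = []
            else:
                run.append(pos)
        if run:
            targets.append(GenomicInterval(p.interval.chrom, run[0], run[-1], p.interval.strand))
    return _mean_coverage(
        [r for r in reads if truth[r.read_id].mature_id is None], targets
    )


def _mean_coverage(reads: list[AlignedRead], targets: list[GenomicInterval]) -> float:
    if not targets:
        return float("nan")
    total_bases = sum(len(iv) for iv in targets)
    covered = 0
    by_chrom: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    for iv in targets:
        for r in by_chrom.get(iv.chrom, []):
            covered += max(0, min(iv.end, r.end) - max(iv.start, r.start) + 1)
    return covered / total_bases


def truth_type(rec: TruthRecord) -> str:
    """IsomiR type implied by a truth record (same taxonomy as the calls)."""
    if rec.mature_id is None:
        return "background"
    kinds = []
    o = rec.offsets or OffsetSignature()
    if o.trim3:
        kinds.append("3p_trim")
    if o.ext3:
        kinds.append("3p_ext")
    if o.trim5:
        kinds.append("5p_trim")
    if o.ext5:
        kinds.append("5p_ext")
    if rec.variant is not None:
        kinds.append("internal_variant")
    if rec.tail_seq:
        kinds.append("tailing")
    if not kinds:
        return "canonical"
    return kinds[0] if len(kinds) == 1 else "combination"


def _call_matches_truth(call: IsomiRCall, rec: TruthRecord) -> bool:
    if rec.mature_id is None:
        return call.status != "assigned"
    if call.status != "assigned" or call.mature_id != rec.mature_id:
        return False
    if call.offsets != (rec.offsets or OffsetSignature()):
        return False
    want_tail = rec.tail_seq or ""
    if call.tail.tail_sequence != want_tail:
        return False
    if rec.variant is None:
        return call.variant is None
    if call.variant is None:
        return False
    pos, ref, alt = rec.variant
    return (call.variant.position, call.variant.ref_base, call.variant.alt_base) == (pos, ref, alt)


def score_performance(
    truth: dict[str, TruthRecord], calls: list[IsomiRCall]
) -> PerfMetrics:
    """Score calls against truth.

    Assignment-level TP/FP/FN follow the benchmark definitions (origin
    miRNA); ``type_accuracy`` additionally requires the full isomiR signature
    (offsets, variant, tail) to match, and counts a background read as
    correct only when left unassigned.
    """
    calls_by_id = {}
    for c in calls:
        calls_by_id[c.read_id] = c
    for rid in calls_by_id:
        if rid not in truth:
            raise SimConfigError(f"call for unknown read id {rid!r}")
    tp = fp = fn = 0
    n_correct = 0
    per_type: dict[str, dict[str, float]] = {}
    for rid, rec in truth.items():
        call = calls_by_id.get(rid, IsomiRCall(rid, "unassigned"))
        ttype = truth_type(rec)
        bucket = per_type.setdefault(ttype, {"tp": 0, "fp": 0, "fn": 0, "n": 0})
        bucket["n"] += 1
        full_match = _call_matches_truth(call, rec)
        if full_match:
            n_correct += 1
        if rec.mature_id is None:
            if call.status == "assigned":
                fp += 1
                bucket["fp"] += 1
            continue
        if call.status == "assigned":
            if call.mature_id == rec.mature_id and full_match:
                tp += 1
                bucket["tp"] += 1
            elif call.mature_id == rec.mature_id:
                tp += 1  # right origin, wrong fine type
                bucket["fn"] += 1  # per-type ledger treats it as a type miss
            else:
                fp += 1
                bucket["fp"] += 1
        else:
            fn += 1
            bucket["fn"] += 1
    for bucket in per_type.values():
        denom_sens = bucket["tp"] + bucket["fn"]
        denom_spec = bucket["tp"] + bucket["fp"]
        bucket["sensitivity"] = bucket["tp"] / denom_sens if denom_sens else float("nan")
        bucket["specificity"] = bucket["tp"] / denom_spec if denom_spec else float("nan")
    return PerfMetrics(
        tp=tp, fp=fp, fn=fn,
        type_accuracy=n_correct / len(truth) if truth else float("nan"),
        per_type=per_type,
    )


# ---------------------------------------------------------------------------
# truth table I/O


def write_truth_tsv(truth: dict[str, TruthRecord], path: str) -> None:
    cols = (
        "read_id\tmature_id\ttrim5\text5\ttrim3\text3\tvar_pos\tvar_ref\tvar_alt\ttail_seq\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for rid in sorted(truth):
            rec = truth[rid]
            o = rec.offsets or OffsetSignature()
            var = rec.variant or (None, None, None)
            fh.write(
                "\t".join(
                    [
                        rid,
                        rec.mature_id or "NA",
                        str(o.trim5), str(o.ext5), str(o.trim3), str(o.ext3),
                        "NA" if var[0] is None else str(var[0]),
                        var[1] or "NA",
                        var[2] or "NA",
                        rec.tail_seq or "NA",
                    ]
                )
                + "\n"
            )


def read_truth_tsv(path: str) -> dict[str, TruthRecord]:
    truth: dict[str, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise SimConfigError(f"{path}: not a truth table")
        for line in fh:
            (rid, mid, t5, e5, t3, e3, vp, vr, va, tail) = line.rstrip("\n").split("\t")
            mature = None if mid == "NA" else mid
            truth[rid] = TruthRecord(
                mature_id=mature,
                offsets=None if mature is None else OffsetSignature(int(t5), int(e5), int(t3), int(e3)),
                variant=None if vp == "NA" else (int(vp), vr, va),
                tail_seq=None if tail == "NA" else tail,
            )
    return truth
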