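"""The isomiR finder: route reads, compute end offsets, attach variants and
tails, encode identifiers, and accumulate count tables.

The algorithm assigns each aligned read to a canonical mature miRNA when both
read ends lie within ``max_shift`` (default 5) nucleotides of the mature's
genomic coordinates.  Reads are routed by mismatch count: mismatch-free reads
are pure end-offset isomiRs; a single internal mismatch is a candidate
internal variant (editing/SNP), confirmed by a quality- and depth-gated
pileup; 1-3 mismatches forming a contiguous run at the transcript 3'
terminus are an untemplated tail (the tail is stripped before the end
offsets are measured); other multi-mismatch patterns are discarded.  Reads
compatible with matures of more than one precursor are ambiguous and kept
out of the primary count table.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .identifier import IsomiRIdentifier, OffsetSignature, decode, encode, isomir_type
from .reference import (
    NCRNA_CLASS_PRECEDENCE,
    GenomicInterval,
    ReferenceBundle,
    dna_to_rna,
)
from .samio import AlignedRead, Mismatch
from .variants import (
    VariantObservation,
    VariantThresholds,
    build_pileup,
    classify_sites,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# routing outcomes
EXACT_PATH = "exact_path"
VARIANT_PATH = "variant_path"
TAILING_PATH = "tailing_path"
DISCARD = "discard"

MAX_MISMATCHES = 3
MAX_TAIL = 3


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class TailCall:
    present: bool = False
    tail_sequence: str = ""  # RNA alphabet

    def __post_init__(self) -> None:
        if self.present != bool(self.tail_sequence):
            raise ClassifierError("tail present flag must mirror a non-empty sequence")
        if len(self.tail_sequence) > MAX_TAIL:
            raise ClassifierError(f"tail longer than {MAX_TAIL} nt")


@dataclass
class IsomiRCall:
    """Outcome of classifying one read (or one multi-hit read group)."""

    read_id: str
    status: str  # assigned | ambiguous | unassigned | discarded
    mature_id: str | None = None
    offsets: OffsetSignature | None = None
    variant: VariantObservation | None = None
    tail: TailCall = field(default_factory=TailCall)
    sequence: str = ""  # full observed read, RNA, transcript orientation
    candidates: tuple[str, ...] = ()  # qualifying mature ids (ambiguous calls)

    @property
    def identifier(self) -> str:
        if self.status != "assigned":
            raise ClassifierError("only assigned calls have an identifier")
        var = self.variant
        return encode(
            IsomiRIdentifier(
                sequence=self.sequence,
                mature_id=self.mature_id,
                offsets=self.offsets,
                variant_position=None if var is None else var.position,
                variant_count=0 if var is None else 1,
                variant_class="none" if var is None else var.classification,
                tail_sequence=self.tail.tail_sequence,
            )
        )


# ---------------------------------------------------------------------------
# routing and tail handling


def route_by_mismatch(read: AlignedRead, max_mismatches: int = MAX_MISMATCHES) -> str:
    """Route a read by its mismatch pattern.

    0 mismatches -> exact path; a contiguous 3'-terminal run of 1-3
    mismatches -> tailing path; a single internal mismatch -> variant path;
    any other 2-3 mismatch pattern -> discard.
    """
    n = len(read.mismatches)
    if n > max_mismatches:
        raise ClassifierError(
            f"read {read.read_id}: {n} mismatches exceeds the configured maximum "
            f"of {max_mismatches}"
        )
    if n == 0:
        return EXACT_PATH
    length = len(read)
    positions = sorted(mm.read_pos for mm in read.mismatches)
    if positions == list(range(length - n + 1, length + 1)):
        return TAILING_PATH
    if n == 1:
        return VARIANT_PATH
    return DISCARD


def detect_tailing(read: AlignedRead) -> tuple[TailCall, GenomicInterval]:
    """Tail call plus the tail-stripped (templated core) interval.

    The tail is the contiguous run of terminal mismatched bases in transcript
    orientation; the returned interval is the alignment with those positions
    removed from the transcript 3' end, against which end offsets are then
    measured.
    """
    n = len(read.mismatches)
    if n == 0:
        return TailCall(), GenomicInterval(read.chrom, read.start, read.end, read.strand)
    length = len(read)
    positions = sorted(mm.read_pos for mm in read.mismatches)
    if positions != list(range(length - n + 1, length + 1)):
        raise ClassifierError(f"read {read.read_id} was not routed to the tailing path")
    for mm in read.mismatches:
        if mm.read_base == mm.ref_base:
            raise ClassifierError(
                f"read {read.read_id}: tail base at {mm.read_pos} matches the template"
            )
    tail_seq = dna_to_rna(read.sequence[length - n :])
    if read.strand == "+":
        core = GenomicInterval(read.chrom, read.start, read.end - n, read.strand)
    else:
        core = GenomicInterval(read.chrom, read.start + n, read.end, read.strand)
    return TailCall(present=True, tail_sequence=tail_seq), core


# ---------------------------------------------------------------------------
# offsets and assignment


def compute_offsets(
    read_interval: GenomicInterval,
    mature_interval: GenomicInterval,
    max_shift: int = 5,
) -> OffsetSignature | None:
    """End offsets of a read against a canonical mature, transcript-oriented.

    Returns ``None`` when either end is shifted by more than ``max_shift``
    (out of range; caller treats the pair as non-matching).
    """
    if read_interval.chrom != mature_interval.chrom:
        return None
    if read_interval.strand != mature_interval.strand:
        return None
    if read_interval.strand == "+":
        d5 = read_interval.start - mature_interval.start  # + => trimmed 5'
        d3 = read_interval.end - mature_interval.end  # + => extended 3'
    else:
        d5 = mature_interval.end - read_interval.end
        d3 = mature_interval.start - read_interval.start
    if abs(d5) > max_shift or abs(d3) > max_shift:
        return None
    return OffsetSignature(
        trim5=max(d5, 0), ext5=max(-d5, 0), trim3=max(-d3, 0), ext3=max(d3, 0)
    )


@dataclass
class Assignment:
    status: str  # assigned | ambiguous | unassigned
    mature_id: str | None = None
    offsets: OffsetSignature | None = None
    candidates: tuple[str, ...] = ()


def assign_interval(
    bundle: ReferenceBundle, core: GenomicInterval, max_shift: int = 5
) -> Assignment:
    """Match one (tail-stripped) alignment interval against annotated matures."""
    cands: list[tuple[str, str, OffsetSignature]] = []  # (precursor, mature, offsets)
    for prec in bundle.precursors_overlapping(core.chrom, core.start, core.end):
        if prec.interval.strand != core.strand:
            continue
        for mat in bundle.matures_of(prec.id):
            offs = compute_offsets(core, mat.interval, max_shift)
            if offs is not None:
                cands.append((prec.id, mat.id, offs))
    precursor_ids = sorted({c[0] for c in cands})
    if not cands:
        return Assignment("unassigned")
    if len(precursor_ids) >= 2:
        return Assignment("ambiguous", candidates=tuple(sorted(c[1] for c in cands)))
    best = min(cands, key=lambda c: (c[2].total_shift, c[1]))
    ties = [c for c in cands if c[2].total_shift == best[2].total_shift]
    if len(ties) > 1:  # two matures of one precursor fit equally well
        return Assignment("ambiguous", candidates=tuple(sorted(c[1] for c in ties)))
    return Assignment("assigned", mature_id=best[1], offsets=best[2])


def assign_read(
    hits: AlignedRead | list[AlignedRead],
    bundle: ReferenceBundle,
    max_shift: int = 5,
) -> Assignment:
    """Assign a read (all alignments of one read id) to a mature miRNA.

    Assigned iff exactly one precursor yields a qualifying mature across all
    hits; two or more qualifying precursors -> ambiguous; none -> unassigned.
    """
    if isinstance(hits, AlignedRead):
        hits = [hits]
    per_hit: list[tuple[AlignedRead, Assignment]] = []
    all_matures: set[str] = set()
    for hit in hits:
        tail_n = _terminal_tail_length(hit)
        if hit.strand == "+":
            core = GenomicInterval(hit.chrom, hit.start, hit.end - tail_n, hit.strand)
        else:
            core = GenomicInterval(hit.chrom, hit.start + tail_n, hit.end, hit.strand)
        a = assign_interval(bundle, core, max_shift)
        per_hit.append((hit, a))
        if a.status == "assigned":
            all_matures.add(a.mature_id)
        elif a.status == "ambiguous":
            all_matures.update(a.candidates)
    precursors = {bundle.matures[m].precursor_id for m in all_matures}
    if not precursors:
        return Assignment("unassigned")
    if len(precursors) >= 2 or any(a.status == "ambiguous" for _, a in per_hit):
        return Assignment("ambiguous", candidates=tuple(sorted(all_matures)))
    for _, a in per_hit:
        if a.status == "assigned":
            return a
    return Assignment("unassigned")  # pragma: no cover


def _terminal_tail_length(read: AlignedRead) -> int:
    """Length of the contiguous 3'-terminal mismatch run (0 if not a tail)."""
    n = len(read.mismatches)
    if not (1 <= n <= MAX_TAIL):
        return 0
    length = len(read)
    positions = sorted(mm.read_pos for mm in read.mismatches)
    if positions == list(range(length - n + 1, length + 1)):
        return n
    return 0


# ---------------------------------------------------------------------------
# ncRNA class filtering


def filter_ncrna(
    reads: list[AlignedRead], bundle: ReferenceBundle
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Drop rRNA-overlapping reads and count reads per ncRNA class.

    Every read is counted toward exactly one class, chosen by the precedence
    rRNA > miRNA > tRNA > snoRNA > SRP_RNA > lncRNA > other, or
    ``unannotated`` when it overlaps no feature.  Only rRNA reads are removed.
    """
    rank = {b: i for i, b in enumerate(NCRNA_CLASS_PRECEDENCE)}
    counts: dict[str, int] = defaultdict(int)
    retained: list[AlignedRead] = []
    for read in reads:
        feats = bundle.ncrna_overlapping(read.chrom, read.start, read.end)
        if not feats:
            counts["unannotated"] += 1
            retained.append(read)
            continue
        cls = min((f.biotype for f in feats), key=lambda b: rank[b])
        counts[cls] += 1
        if cls != "rRNA":
            retained.append(read)
    return retained, dict(counts)


# ---------------------------------------------------------------------------
# full per-sample pipeline


def classify_reads(
    reads: list[AlignedRead],
    bundle: ReferenceBundle,
    max_shift: int = 5,
    max_mismatches: int = MAX_MISMATCHES,
    thresholds: VariantThresholds = VariantThresholds(),
) -> list[IsomiRCall]:
    """Classify one sample's reads into isomiR calls.

    Reads sharing a read id are treated as one multi-mapping group.  The
    exact path is processed first, then single-mismatch (variant) reads —
    whose mismatches are confirmed jointly through a pileup over all
    quality-passing reads — and finally terminal-mismatch (tailing) reads.
    Status conservation holds: every input read group ends as exactly one of
    assigned / ambiguous / unassigned / discarded.
    """
    groups: dict[str, list[AlignedRead]] = defaultdict(list)
    order: list[str] = []
    for read in reads:
        if read.read_id not in groups:
            order.append(read.read_id)
        groups[read.read_id].append(read)

    calls: dict[str, IsomiRCall] = {}
    variant_pending: list[tuple[str, AlignedRead, Mismatch, Assignment]] = []

    for rid in order:
        hits = groups[rid]
        primary = hits[0]
        seq_rna = dna_to_rna(primary.sequence)
        if len(primary.mismatches) > max_mismatches:
            calls[rid] = IsomiRCall(rid, "discarded", sequence=seq_rna)
            continue
        route = route_by_mismatch(primary, max_mismatches)
        if route == DISCARD:
            calls[rid] = IsomiRCall(rid, "discarded", sequence=seq_rna)
            continue
        assignment = assign_read(hits, bundle, max_shift)
        if assignment.status != "assigned":
            calls[rid] = IsomiRCall(
                rid, assignment.status, sequence=seq_rna, candidates=assignment.candidates
            )
            continue
        if route == TAILING_PATH:
            tail, _ = detect_tailing(primary)
            calls[rid] = IsomiRCall(
                rid, "assigned", assignment.mature_id, assignment.offsets,
                tail=tail, sequence=seq_rna,
            )
        elif route == VARIANT_PATH:
            mm = primary.mismatches[0]
            variant_pending.append((rid, primary, mm, assignment))
            calls[rid] = IsomiRCall(
                rid, "assigned", assignment.mature_id, assignment.offsets, sequence=seq_rna
            )
        else:  # exact
            calls[rid] = IsomiRCall(
                rid, "assigned", assignment.mature_id, assignment.offsets, sequence=seq_rna
            )

    if variant_pending:
        sites = build_pileup(
            reads, bundle, thresholds,
            candidate_mismatches=[(r, mm) for _, r, mm, _ in variant_pending],
        )
        site_class = classify_sites(sites, bundle, thresholds)
        for rid, read, mm, _ in variant_pending:
            alt_fwd = mm.read_base if read.strand == "+" else _COMPLEMENT[mm.read_base]
            cls, depth, alt_count = site_class.get(
                (read.chrom, mm.genomic_pos, alt_fwd), ("none", 0, 0)
            )
            if cls != "none":
                calls[rid].variant = VariantObservation(
                    position=mm.read_pos,
                    ref_base=mm.ref_base,
                    alt_base=mm.read_base,
                    classification=cls,
                    depth=depth,
                    alt_count=alt_count,
                )
    return [calls[rid] for rid in order]


# ---------------------------------------------------------------------------
# count tables and summaries


def _ambiguous_key(call: IsomiRCall) -> str:
    return f"{call.sequence}|{';'.join(sorted(call.candidates))}"


def accumulate_counts(
    calls_by_sample: dict[str, list[IsomiRCall]],
    condition_map: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build (unambiguous, ambiguous) identifier-by-replicate count matrices.

    Columns are sample names ordered by (condition, sample); unambiguous rows
    are 11-field identifiers, ambiguous rows are keyed by read sequence plus
    the sorted candidate matures.
    """
    for sample in calls_by_sample:
        if sample not in condition_map:
            raise ClassifierError(f"sample {sample!r} missing from the condition map")
    samples = sorted(calls_by_sample, key=lambda s: (condition_map[s], s))
    unamb: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    amb: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for sample in samples:
        for call in calls_by_sample[sample]:
            if call.status == "assigned":
                unamb[call.identifier][sample] += 1
            elif call.status == "ambiguous":
                amb[_ambiguous_key(call)][sample] += 1

    def _frame(data: dict[str, dict[str, int]]) -> pd.DataFrame:
        df = pd.DataFrame(
            {s: {k: v.get(s, 0) for k, v in data.items()} for s in samples},
            dtype="int64",
        )
        if df.empty:
            df = pd.DataFrame(columns=samples, dtype="int64")
        df.index.name = "isomiR_ID"
        return df.sort_index()

    return _frame(unamb), _frame(amb)


def summarize_types(
    counts: pd.DataFrame, condition_map: dict[str, str]
) -> pd.DataFrame:
    """Per-condition proportions of isomiR types from an unambiguous matrix.

    A row with more than one deviation kind counts once under
    ``combination``; proportions within a condition sum to 1.
    """
    if counts.empty or int(counts.to_numpy().sum()) == 0:
        raise ClassifierError("cannot summarize an all-zero count matrix")
    types = [isomir_type(decode(ident)) for ident in counts.index]
    by_type = counts.groupby(pd.Index(types, name="type")).sum()
    conditions = sorted(set(condition_map[s] for s in counts.columns))
    out = pd.DataFrame(index=by_type.index, columns=conditions, dtype=float)
    for cond in conditions:
        cols = [s for s in counts.columns if condition_map[s] == cond]
        total = by_type[cols].to_numpy().sum()
        if total == 0:
            out[cond] = 0.0
        else:
            out[cond] = by_type[cols].sum(axis=1) / total
    return out


def arm_proportions(
    counts: pd.DataFrame, bundle: ReferenceBundle, condition_map: dict[str, str]
) -> pd.DataFrame:
    """Per-condition 5p/3p read fractions from an unambiguous matrix."""
    arms = []
    for ident in counts.index:
        mature = decode(ident).mature_id
        if mature not in bundle.matures:
            raise ClassifierError(f"mature id {mature!r} not present in the reference")
        arms.append(bundle.matures[mature].arm)
    by_arm = counts.groupby(pd.Index(arms, name="arm")).sum()
    by_arm = by_arm.reindex(["5p", "3p"], fill_value=0)
    conditions = sorted(set(condition_map[s] for s in counts.columns))
    out = pd.DataFrame(index=by_arm.index, columns=conditions, dtype=float)
    for cond in conditions:
        cols = [s for s in counts.columns if condition_map[s] == cond]
        total = by_arm[cols].to_numpy().sum()
        out[cond] = by_arm[cols].sum(axis=1) / total if total else 0.0
    return out
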