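"""SAM input/output for aligned small-RNA reads.

Reads are represented in *transcript orientation*: ``sequence`` and ``quals``
run 5'->3' along the transcript (for minus-strand alignments this is the
reverse complement of the SAM SEQ field), and mismatch positions are 1-based
within the read in that orientation.  Mismatches are recomputed against the
reference genome, so MD/NM tags are not required.

Soft clips are tolerated only at the transcript 3' terminus and only up to 3
nt (candidate untemplated tails); such clipped bases are re-attached as
aligned bases so the downstream mismatch router sees them as terminal
mismatches (or templated extensions).  Any 5' clip, longer clip, or gapped
CIGAR discards the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .reference import ReferenceBundle, dna_to_rna, reverse_complement


@dataclass(frozen=True)
class Mismatch:
    read_pos: int  # 1-based, transcript orientation
    genomic_pos: int  # 1-based, forward genome
    ref_base: str  # transcript orientation (DNA)
    read_base: str  # transcript orientation (DNA)
    base_quality: int


@dataclass
class AlignedRead:
    """One alignment of one read, transcript-oriented."""

    read_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    sequence: str  # transcript orientation, DNA alphabet
    quals: list[int] = field(default_factory=list)
    mapping_quality: int = 42
    num_hits: int = 1
    mismatches: list[Mismatch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def sequence_rna(self) -> str:
        return dna_to_rna(self.sequence)

    def genomic_pos(self, read_pos: int) -> int:
        """Forward-genome coordinate of a 1-based transcript position."""
        if self.strand == "+":
            return self.start + read_pos - 1
        return self.end - read_pos + 1

    def qual_at_genomic(self, gpos: int) -> int:
        if self.strand == "+":
            i = gpos - self.start
        else:
            i = self.end - gpos
        if not self.quals:
            return 40
        return self.quals[i]

    def covers(self, gpos: int) -> bool:
        return self.start <= gpos <= self.end


def compute_mismatches(read: AlignedRead, bundle: ReferenceBundle) -> list[Mismatch]:
    """Recompute the mismatch list of ``read`` against the bundle genome."""
    ref_fwd = bundle.fetch(read.chrom, read.start, read.end)
    ref_txn = reverse_complement(ref_fwd) if read.strand == "-" else ref_fwd
    mms = []
    for i, (rb, gb) in enumerate(zip(read.sequence.upper(), ref_txn), start=1):
        if rb != gb:
            bq = read.quals[i - 1] if read.quals else 40
            mms.append(Mismatch(i, read.genomic_pos(i), gb, rb, bq))
    return mms


def _from_alignment(
    aln: pysam.AlignedSegment, bundle: ReferenceBundle, max_soft_clip: int = 3
) -> AlignedRead | None:
    """Convert one SAM record; returns None when the record must be discarded."""
    if aln.is_unmapped or aln.query_sequence is None:
        return None
    cigar = aln.cigartuples or []
    ops = {op for op, _ in cigar}
    if not ops <= {0, 4, 7, 8}:  # M, S, =, X only
        return None
    lead_clip = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
    tail_clip = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
    strand = "-" if aln.is_reverse else "+"
    # transcript 3' terminus is SAM-right for + reads, SAM-left for - reads
    clip3 = tail_clip if strand == "+" else lead_clip
    clip5 = lead_clip if strand == "+" else tail_clip
    if clip5 > 0 or clip3 > max_soft_clip:
        return None
    start = aln.reference_start + 1  # to 1-based
    end = aln.reference_end  # pysam reference_end is 0-based exclusive == 1-based incl.
    seq_fwd = aln.query_sequence.upper()
    quals_fwd = list(aln.query_qualities) if aln.query_qualities is not None else []
    if clip3:
        # re-attach clipped bases as aligned bases extending the interval
        if strand == "+":
            end += clip3
        else:
            start -= clip3
        if start < 1:
            return None
        chrom_len = len(bundle.genome.get(aln.reference_name, ""))
        if end > chrom_len:
            return None
    if strand == "-":
        seq = reverse_complement(seq_fwd)
        quals = quals_fwd[::-1]
    else:
        seq = seq_fwd
        quals = quals_fwd
    try:
        nh = aln.get_tag("NH")
    except KeyError:
        nh = 1
    read = AlignedRead(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        start=start,
        end=end,
        strand=strand,
        sequence=seq,
        quals=quals,
        mapping_quality=aln.mapping_quality,
        num_hits=int(nh),
    )
    read.mismatches = compute_mismatches(read, bundle)
    return read


def read_sam(path: str, bundle: ReferenceBundle) -> tuple[list[AlignedRead], int]:
    """Load a SAM file.

    Returns ``(reads, n_discarded)`` where discarded records are unmapped,
    gapped, or clipped beyond the tolerated 3'-tail window.
    """
    reads: list[AlignedRead] = []
    discarded = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            rec = _from_alignment(aln, bundle)
            if rec is None:
                discarded += 1
            else:
                reads.append(rec)
    return reads, discarded


def write_sam(path: str, reads: list[AlignedRead], bundle: ReferenceBundle) -> None:
    """Write reads as an uncompressed SAM file with a header from the bundle."""
    chroms = sorted(bundle.genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(bundle.genome[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = read.read_id
            aln.flag = 16 if read.strand == "-" else 0
            aln.reference_id = tid[read.chrom]
            aln.reference_start = read.start - 1
            aln.mapping_quality = read.mapping_quality
            aln.cigarstring = f"{len(read.sequence)}M"
            if read.strand == "-":
                aln.query_sequence = reverse_complement(read.sequence)
                aln.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in reversed(read.quals))
                ) if read.quals else None
            else:
                aln.query_sequence = read.sequence
                aln.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.quals)
                ) if read.quals else None
            aln.set_tag("NH", read.num_hits)
            aln.set_tag("NM", len(read.mismatches))
            out.write(aln)
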