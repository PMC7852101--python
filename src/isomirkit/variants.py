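"""Pileup-based internal-variant detection and classification.

A self-contained reimplementation of the samtools/bcftools filtering stage
with the four stated cutoffs: observations are quality-gated at mapping
quality >= 20 and base quality >= 20, bona fide variants require depth >= 10
and >= 3 alternate-supporting reads, and sites failing those thresholds are
still reported as ALT when >= 1000 reads support the alternate allele.

Confirmed sites are classified, in order of precedence:

1. ``dbSNP`` — (chrom, pos, ref, alt) present in the known-variant catalogue;
2. ``A_to_I_editing`` — transcript-orientation A->G transition (animal mode
   only; A-to-I editing reads as A->G in sequencing data);
3. ``novel_SNP`` — anything else.

Plant bundles carry no catalogue and never emit editing calls.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .reference import ReferenceBundle, reverse_complement
from .samio import AlignedRead

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class VariantThresholds:
    """Caller cutoffs; defaults mirror ``-q20 -Q20 -d10 -a3`` plus the
    1000-read ALT reporting rule."""

    min_mapping_quality: int = 20
    min_base_quality: int = 20
    min_depth: int = 10
    min_alt_reads: int = 3
    alt_report_support: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "min_mapping_quality", "min_base_quality",
            "min_depth", "min_alt_reads", "alt_report_support",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PileupSite:
    """One genomic site with quality-gated observations (forward orientation)."""

    chrom: str
    position: int
    ref_base: str  # forward genome
    strand: str  # strand of the transcript the site lies on
    depth: int = 0
    alt_counts: dict[str, int] = field(default_factory=dict)

    @property
    def top_alt(self) -> str:
        # highest support, ties broken alphabetically for determinism
        return min(self.alt_counts, key=lambda b: (-self.alt_counts[b], b))

    @property
    def top_alt_count(self) -> int:
        return self.alt_counts[self.top_alt]


@dataclass(frozen=True)
class VariantObservation:
    """A classified variant as attached to a single read's isomiR call."""

    position: int  # 1-based transcript position within the read
    ref_base: str  # transcript orientation (DNA)
    alt_base: str
    classification: str  # dbSNP | A_to_I_editing | novel_SNP | ALT | none
    depth: int
    alt_count: int


def build_pileup(
    reads: list[AlignedRead],
    bundle: ReferenceBundle,
    thresholds: VariantThresholds = VariantThresholds(),
    candidate_mismatches=None,
) -> list[PileupSite]:
    """Quality-gated pileup over mismatched sites.

    ``candidate_mismatches`` optionally restricts alternate observations to an
    iterable of ``(read, Mismatch)`` pairs (e.g. internal mismatches of
    variant-routed reads); by default every mismatch of every read
    contributes.  Depth at a site counts all reads — matching or not — that
    pass the quality gates and cover it.
    """
    if candidate_mismatches is None:
        candidate_mismatches = [(r, mm) for r in reads for mm in r.mismatches]

    alt_obs: dict[tuple[str, int], dict[str, int]] = defaultdict(lambda: defaultdict(int))
    site_strand: dict[tuple[str, int], str] = {}
    for read, mm in candidate_mismatches:
        if read.mapping_quality < thresholds.min_mapping_quality:
            continue
        if mm.base_quality < thresholds.min_base_quality:
            continue
        # record in forward-genome orientation so dbSNP lookup is direct
        alt_fwd = mm.read_base if read.strand == "+" else _COMPLEMENT[mm.read_base]
        alt_obs[(read.chrom, mm.genomic_pos)][alt_fwd] += 1
        site_strand[(read.chrom, mm.genomic_pos)] = read.strand

    if not alt_obs:
        return []

    # depth: quality-passing coverage per chromosome, computed with
    # difference arrays (per-base only for reads with low-quality bases)
    depth_arrays: dict[str, np.ndarray] = {}
    needed_chroms = {chrom for chrom, _ in alt_obs}
    for chrom in needed_chroms:
        depth_arrays[chrom] = np.zeros(len(bundle.genome[chrom]) + 2, dtype=np.int64)
    for read in reads:
        if read.chrom not in depth_arrays:
            continue
        if read.mapping_quality < thresholds.min_mapping_quality:
            continue
        arr = depth_arrays[read.chrom]
        if not read.quals or min(read.quals) >= thresholds.min_base_quality:
            arr[read.start] += 1
            arr[read.end + 1] -= 1
        else:
            for i, q in enumerate(read.quals):
                if q >= thresholds.min_base_quality:
                    gpos = read.genomic_pos(i + 1)
                    arr[gpos] += 1
                    arr[gpos + 1] -= 1
    coverage = {chrom: np.cumsum(arr) for chrom, arr in depth_arrays.items()}

    sites = []
    for (chrom, gpos) in sorted(alt_obs):
        counts = dict(alt_obs[(chrom, gpos)])
        sites.append(
            PileupSite(
                chrom=chrom,
                position=gpos,
                ref_base=bundle.fetch(chrom, gpos, gpos),
                strand=site_strand[(chrom, gpos)],
                depth=int(coverage[chrom][gpos]),
                alt_counts=counts,
            )
        )
    return sites


def filter_bona_fide(site: PileupSite, thresholds: VariantThresholds = VariantThresholds()) -> bool:
    """Bona fide test: depth >= min_depth and top-alt support >= min_alt_reads."""
    return site.depth >= thresholds.min_depth and site.top_alt_count >= thresholds.min_alt_reads


def classify_variant(site: PileupSite, bundle: ReferenceBundle, alt: str | None = None) -> str:
    """Classify a bona fide site: dbSNP beats editing beats novel SNP."""
    alt = alt or site.top_alt
    if bundle.known_variants is not None and (
        site.chrom, site.position, site.ref_base, alt
    ) in bundle.known_variants:
        return "dbSNP"
    if bundle.taxon_mode == "animal":
        if site.strand == "+":
            ref_txn, alt_txn = site.ref_base, alt
        else:
            ref_txn, alt_txn = _COMPLEMENT[site.ref_base], _COMPLEMENT[alt]
        if ref_txn == "A" and alt_txn == "G":
            return "A_to_I_editing"
    return "novel_SNP"


def report_alt(site: PileupSite, thresholds: VariantThresholds = VariantThresholds()) -> str:
    """ALT rule for sites that failed the bona fide filter."""
    if filter_bona_fide(site, thresholds):
        return "none"  # a passing site is never ALT
    if site.top_alt_count >= thresholds.alt_report_support:
        return "ALT"
    return "none"


def classify_sites(
    sites: list[PileupSite],
    bundle: ReferenceBundle,
    thresholds: VariantThresholds = VariantThresholds(),
) -> dict[tuple[str, int, str], tuple[str, int, int]]:
    """Total classification of every site/alt combination.

    Returns ``{(chrom, pos, alt_fwd): (class, depth, alt_count)}`` where class
    is one of dbSNP / A_to_I_editing / novel_SNP / ALT / none.
    """
    out: dict[tuple[str, int, str], tuple[str, int, int]] = {}
    for site in sites:
        for alt, count in site.alt_counts.items():
            if site.depth >= thresholds.min_depth and count >= thresholds.min_alt_reads:
                cls = classify_variant(site, bundle, alt)
            elif count >= thresholds.alt_report_support:
                cls = "ALT"
            else:
                cls = "none"
            out[(site.chrom, site.position, alt)] = (cls, site.depth, count)
    return out
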