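"""Post-processing of novel-miRNA precursor candidates.

The prediction itself is external; this module resolves overlapping
predictions (reciprocal overlap >= 90% keeps only the higher-coverage
candidate), annotates candidates with overlapping known ncRNAs, and matches
candidate seeds (mature positions 2-8) against known miRNAs of other species.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference import GenomicInterval, ReferenceBundle, mature_seed


@dataclass(frozen=True)
class NovelCandidate:
    id: str
    interval: GenomicInterval
    read_coverage: int
    mature_sequence: str | None = None  # RNA

    def __post_init__(self) -> None:
        if self.read_coverage < 0:
            raise ValueError("read_coverage must be >= 0")


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Shared length as a fraction of the shorter interval (0 when disjoint)."""
    shared = a.overlap_length(b)
    if shared == 0:
        return 0.0
    return shared / min(len(a), len(b))


def merge_overlapping(
    candidates: list[NovelCandidate], min_overlap_fraction: float = 0.90
) -> list[NovelCandidate]:
    """Resolve overlapping predictions, keeping the higher-coverage member.

    For any pair with reciprocal overlap >= the threshold only the candidate
    with more supporting reads survives (ties broken toward the
    lexicographically smaller id).  Applied transitively to a fixpoint; the
    result is deterministic and independent of input order.
    """
    # process best-first: a retained candidate then suppresses its overlaps
    ranked = sorted(candidates, key=lambda c: (-c.read_coverage, c.id))
    retained: list[NovelCandidate] = []
    for cand in ranked:
        if any(
            _reciprocal_overlap(cand.interval, kept.interval) >= min_overlap_fraction
            for kept in retained
        ):
            continue
        retained.append(cand)
    return sorted(retained, key=lambda c: c.id)


def intersect_with_ncrna(
    candidates: list[NovelCandidate], bundle: ReferenceBundle
) -> dict[str, list[tuple[str, str]]]:
    """Label each candidate with overlapping ncRNA (id, biotype) pairs."""
    out: dict[str, list[tuple[str, str]]] = {}
    for cand in candidates:
        iv = cand.interval
        feats = bundle.ncrna_overlapping(iv.chrom, iv.start, iv.end)
        out[cand.id] = [(f.id, f.biotype) for f in feats]
    return out


def match_seed_to_known(
    candidates: list[NovelCandidate], foreign_seed_table: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Exact 7-mer seed lookup against known miRNAs of other species.

    Candidates without a mature sequence, or with one shorter than 8 nt, are
    skipped (empty match list).
    """
    out: dict[str, list[str]] = {}
    for cand in candidates:
        seq = cand.mature_sequence
        if not seq or len(seq) < 8:
            out[cand.id] = []
            continue
        seed = mature_seed(seq)
        out[cand.id] = sorted(foreign_seed_table.get(seed, []))
    return out


def load_candidates_tsv(path: str) -> list[NovelCandidate]:
    """Read candidates from a TSV: id, chrom, start, end, strand, coverage[, mature_seq]."""
    cands: list[NovelCandidate] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 columns")
            cid, chrom, start, end, strand, cov = parts[:6]
            mature = parts[6] if len(parts) > 6 and parts[6] not in ("", "NA") else None
            cands.append(
                NovelCandidate(
                    id=cid,
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    read_coverage=int(cov),
                    mature_sequence=mature,
                )
            )
    return cands


def write_candidates_tsv(
    path: str,
    candidates: list[NovelCandidate],
    ncrna_overlaps: dict[str, list[tuple[str, str]]] | None = None,
    seed_matches: dict[str, list[str]] | None = None,
) -> None:
    """Write retained candidates with their annotation columns."""
    with open(path, "w") as fh:
        fh.write(
            "id\tchrom\tstart\tend\tstrand\tcoverage\tmature_seq\t"
            "ncRNA_overlaps\tseed_matches\n"
        )
        for cand in candidates:
            iv = cand.interval
            overlaps = (ncrna_overlaps or {}).get(cand.id, [])
            seeds = (seed_matches or {}).get(cand.id, [])
            fh.write(
                "\t".join(
                    [
                        cand.id, iv.chrom, str(iv.start), str(iv.end), iv.strand,
                        str(cand.read_coverage), cand.mature_sequence or "NA",
                        ";".join(f"{i}({b})" for i, b in overlaps) or "NA",
                        ";".join(seeds) or "NA",
                    ]
                )
                + "\n"
            )
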