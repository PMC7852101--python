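"""Shared fixtures: a tiny hand-built reference and small simulation runs."""

from __future__ import annotations

import numpy as np
import pytest

from isomirkit.reference import (
    GenomicInterval,
    KnownVariantStore,
    MatureRecord,
    NcRnaFeature,
    PrecursorRecord,
    ReferenceBundle,
)
from isomirkit.samio import AlignedRead, compute_mismatches
from isomirkit.simulate import (
    SimConfig,
    inject_variants_and_tails,
    simulate_reads,
    simulate_reference,
)


def _det_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def tiny_genome() -> dict[str, str]:
    return {"chr1": _det_seq(400, seed=42), "chr2": _det_seq(300, seed=43)}


@pytest.fixture()
def tiny_bundle(tiny_genome) -> ReferenceBundle:
    """Two precursors (one per strand, different chromosomes) plus an rRNA."""
    genome = tiny_genome
    prec1 = PrecursorRecord(
        id="mir-a",
        interval=GenomicInterval("chr1", 101, 180, "+"),
        sequence="",
        matures=["miR-a-5p", "miR-a-3p"],
    )
    prec2 = PrecursorRecord(
        id="mir-b",
        interval=GenomicInterval("chr2", 51, 130, "-"),
        sequence="",
        matures=["miR-b-5p"],
    )
    matures = {
        "miR-a-5p": MatureRecord(
            "miR-a-5p", "mir-a", GenomicInterval("chr1", 110, 131, "+"), "5p", ""
        ),
        "miR-a-3p": MatureRecord(
            "miR-a-3p", "mir-a", GenomicInterval("chr1", 149, 170, "+"), "3p", ""
        ),
        "miR-b-5p": MatureRecord(
            "miR-b-5p", "mir-b", GenomicInterval("chr2", 100, 121, "-"), "5p", ""
        ),
    }
    # fill sequences from the genome before running full validation
    import isomirkit.reference as ref

    for rec in [prec1, prec2, *matures.values()]:
        iv = rec.interval
        raw = genome[iv.chrom][iv.start - 1 : iv.end]
        if iv.strand == "-":
            raw = ref.reverse_complement(raw)
        rec.sequence = ref.dna_to_rna(raw)
    ncrna = [
        NcRnaFeature("rrna-1", "rRNA", GenomicInterval("chr1", 300, 360, "+")),
        NcRnaFeature("mirfeat-a", "miRNA", GenomicInterval("chr1", 101, 180, "+")),
        NcRnaFeature("mirfeat-b", "miRNA", GenomicInterval("chr2", 51, 130, "-")),
        NcRnaFeature("lnc-1", "lncRNA", GenomicInterval("chr2", 200, 260, "+")),
    ]
    store = KnownVariantStore()
    return ReferenceBundle(
        genome=genome,
        precursors={"mir-a": prec1, "mir-b": prec2},
        matures=matures,
        ncrna=ncrna,
        known_variants=store,
        taxon_mode="animal",
    )


def make_read(
    bundle: ReferenceBundle,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    read_id: str = "r1",
    mutations: dict[int, str] | None = None,
    quals: list[int] | None = None,
    mapq: int = 42,
) -> AlignedRead:
    """Templated read at the given interval with optional substitutions
    (1-based transcript position -> new base)."""
    import isomirkit.reference as ref

    raw = bundle.fetch(chrom, start, end)
    seq = ref.reverse_complement(raw) if strand == "-" else raw
    if mutations:
        chars = list(seq)
        for pos, base in mutations.items():
            chars[pos - 1] = base
        seq = "".join(chars)
    read = AlignedRead(
        read_id=read_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        sequence=seq,
        quals=quals if quals is not None else [40] * len(seq),
        mapping_quality=mapq,
    )
    read.mismatches = compute_mismatches(read, bundle)
    return read


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulation (2 precursors, reduced depth)."""
    cfg = SimConfig(
        n_precursors=2, mature_depth=2500, hairpin_depth=100,
        snv_fraction=0.4, tail_fraction=0.2, rng_seed=5,
    )
    bundle = simulate_reference(cfg)
    reads, truth = simulate_reads(bundle, cfg)
    reads, truth = inject_variants_and_tails(reads, truth, cfg, bundle)
    return cfg, bundle, reads, truth
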