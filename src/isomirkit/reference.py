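"""Reference bundle: genome, miRNA annotation, ncRNA features and known variants.

Loads a genome FASTA, a miRBase-dialect miRNA GFF3 (``miRNA_primary_transcript``
parents with ``miRNA`` children linked via ``Derives_from``/``Parent``), an
optional ncRNA annotation (GFF3 or BED) and an optional known-SNP catalogue
(VCF), and validates everything into a coordinate-queryable
:class:`ReferenceBundle`.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (SAM/GFF native); BED input is
  converted on read.
* Transcript-orientation sequences (mature/precursor) use the RNA alphabet;
  genome slices stay DNA.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Mapping

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree

NCRNA_BIOTYPES = ("rRNA", "miRNA", "lncRNA", "SRP_RNA", "tRNA", "snoRNA", "other")

#: precedence used when a read overlaps features of several classes
NCRNA_CLASS_PRECEDENCE = ("rRNA", "miRNA", "tRNA", "snoRNA", "SRP_RNA", "lncRNA", "other")


class ReferenceError(ValueError):
    """Raised when a reference file fails validation."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ReferenceError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ReferenceError(
                f"interval end {self.end} precedes start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ReferenceError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class MatureRecord:
    id: str
    precursor_id: str
    interval: GenomicInterval
    arm: str
    sequence: str  # RNA alphabet, transcript orientation

    @property
    def seed(self) -> str:
        return mature_seed(self)


@dataclass
class PrecursorRecord:
    id: str
    interval: GenomicInterval
    sequence: str  # RNA alphabet, transcript orientation
    matures: list[str] = field(default_factory=list)


@dataclass
class NcRnaFeature:
    id: str
    biotype: str
    interval: GenomicInterval


class KnownVariantStore:
    """Exact-lookup set of known (chrom, pos, ref, alt) variants, e.g. dbSNP."""

    def __init__(self, records=()) -> None:
        self._records: set[tuple[str, int, str, str]] = set(records)

    def add(self, chrom: str, pos: int, ref: str, alt: str) -> None:
        self._records.add((chrom, int(pos), ref.upper(), alt.upper()))

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        chrom, pos, ref, alt = key
        return (chrom, int(pos), ref.upper(), alt.upper()) in self._records

    def __len__(self) -> int:
        return len(self._records)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


class ReferenceBundle:
    """Genome + annotation, indexed for coordinate queries.

    Parameters
    ----------
    genome
        Mapping of chromosome name to (DNA) sequence string.
    taxon_mode
        ``"animal"`` or ``"plant"``.  Plant mode carries no variant catalogue
        and disables A-to-I editing calls downstream.
    """

    def __init__(
        self,
        genome: Mapping[str, str],
        precursors: dict[str, PrecursorRecord],
        matures: dict[str, MatureRecord],
        ncrna: list[NcRnaFeature] | None = None,
        known_variants: KnownVariantStore | None = None,
        taxon_mode: str = "animal",
    ) -> None:
        if taxon_mode not in ("animal", "plant"):
            raise ReferenceError(f"taxon_mode must be animal|plant, got {taxon_mode!r}")
        if taxon_mode == "plant" and known_variants is not None and len(known_variants):
            raise ReferenceError("plant mode does not accept a known-variant catalogue")
        self.genome = genome
        self.precursors = precursors
        self.matures = matures
        self.ncrna = list(ncrna or [])
        self.known_variants = known_variants if taxon_mode == "animal" else None
        if self.known_variants is None and taxon_mode == "animal":
            self.known_variants = KnownVariantStore()
        self.taxon_mode = taxon_mode
        self._validate()
        self._precursor_tree: dict[str, IntervalTree] = {}
        for prec in precursors.values():
            tree = self._precursor_tree.setdefault(prec.interval.chrom, IntervalTree())
            tree.addi(prec.interval.start, prec.interval.end + 1, prec.id)
        self._ncrna_tree: dict[str, IntervalTree] = {}
        for feat in self.ncrna:
            tree = self._ncrna_tree.setdefault(feat.interval.chrom, IntervalTree())
            tree.addi(feat.interval.start, feat.interval.end + 1, feat)

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        for prec in self.precursors.values():
            if prec.interval.chrom not in self.genome:
                raise ReferenceError(
                    f"precursor {prec.id}: chromosome {prec.interval.chrom!r} "
                    "absent from genome"
                )
            if len(prec.sequence) != len(prec.interval):
                raise ReferenceError(
                    f"precursor {prec.id}: sequence length {len(prec.sequence)} "
                    f"!= interval length {len(prec.interval)}"
                )
        for mat in self.matures.values():
            if mat.precursor_id not in self.precursors:
                raise ReferenceError(
                    f"mature {mat.id}: unknown precursor {mat.precursor_id!r}"
                )
            parent = self.precursors[mat.precursor_id]
            if not parent.interval.contains(mat.interval):
                raise ReferenceError(
                    f"mature {mat.id} not contained in precursor {parent.id} "
                    "on the same strand"
                )
            if mat.arm not in ("5p", "3p"):
                raise ReferenceError(f"mature {mat.id}: arm must be 5p|3p, got {mat.arm!r}")
        for feat in self.ncrna:
            if feat.biotype not in NCRNA_BIOTYPES:
                raise ReferenceError(f"ncRNA {feat.id}: unknown biotype {feat.biotype!r}")
            if feat.interval.chrom not in self.genome:
                raise ReferenceError(
                    f"ncRNA {feat.id}: chromosome {feat.interval.chrom!r} absent from genome"
                )

    # -- queries ----------------------------------------------------------
    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Genomic (forward-strand DNA) slice, 1-based inclusive."""
        if chrom not in self.genome:
            raise ReferenceError(f"chromosome {chrom!r} absent from genome")
        seq = self.genome[chrom]
        if end > len(seq):
            raise ReferenceError(
                f"slice {chrom}:{start}-{end} beyond chromosome length {len(seq)}"
            )
        return str(seq[start - 1 : end]).upper()

    def extract_sequence(self, interval: GenomicInterval) -> str:
        """Transcript-orientation RNA sequence of an interval."""
        raw = self.fetch(interval.chrom, interval.start, interval.end)
        if interval.strand == "-":
            raw = reverse_complement(raw)
        return dna_to_rna(raw)

    def precursors_overlapping(self, chrom: str, start: int, end: int) -> list[PrecursorRecord]:
        tree = self._precursor_tree.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.precursors[iv.data] for iv in tree.overlap(start, end + 1)),
            key=lambda p: p.id,
        )

    def ncrna_overlapping(self, chrom: str, start: int, end: int) -> list[NcRnaFeature]:
        tree = self._ncrna_tree.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end + 1)), key=lambda f: f.id)

    def matures_of(self, precursor_id: str) -> list[MatureRecord]:
        return [self.matures[m] for m in self.precursors[precursor_id].matures]


def mature_seed(mature: MatureRecord | str) -> str:
    """Seed region: transcript positions 2-8 (7 nt) of the mature sequence."""
    seq = mature if isinstance(mature, str) else mature.sequence
    if len(seq) < 8:
        raise ReferenceError(f"sequence too short for a seed ({len(seq)} < 8 nt)")
    return seq[1:8]


# ---------------------------------------------------------------------------
# loaders


def _load_fasta(path: str) -> dict[str, str]:
    import pyfaidx

    fasta = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def _check_gff_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ReferenceError(f"{path}: malformed GFF line {lineno}: expected 9 columns")


def _gff_db(path: str) -> gffutils.FeatureDB:
    _check_gff_lines(path)
    try:
        return gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils raises varied types
        raise ReferenceError(f"{path}: failed to parse GFF3 ({exc})") from exc


def _infer_arm(name: str, mature_iv: GenomicInterval, prec_iv: GenomicInterval) -> str:
    lowered = name.lower()
    if lowered.endswith("-5p") or lowered.endswith("_5p"):
        return "5p"
    if lowered.endswith("-3p") or lowered.endswith("_3p"):
        return "3p"
    # fall back to position: 5p is nearer the precursor 5' end
    if prec_iv.strand == "+":
        d5 = mature_iv.start - prec_iv.start
        d3 = prec_iv.end - mature_iv.end
    else:
        d5 = prec_iv.end - mature_iv.end
        d3 = mature_iv.start - prec_iv.start
    return "5p" if d5 <= d3 else "3p"


def load_mirna_gff(path: str, bundle_genome: Mapping[str, str]) -> tuple[dict, dict]:
    """Parse a miRBase-dialect GFF3 into precursor/mature record dicts."""
    db = _gff_db(path)
    genome_view = bundle_genome
    precursors: dict[str, PrecursorRecord] = {}
    matures: dict[str, MatureRecord] = {}

    def _seq(iv: GenomicInterval) -> str:
        if iv.chrom not in genome_view:
            raise ReferenceError(f"annotation chromosome {iv.chrom!r} absent from genome")
        raw = str(genome_view[iv.chrom][iv.start - 1 : iv.end]).upper()
        if iv.strand == "-":
            raw = reverse_complement(raw)
        return dna_to_rna(raw)

    for feat in db.features_of_type("miRNA_primary_transcript"):
        iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        fid = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        precursors[fid] = PrecursorRecord(id=fid, interval=iv, sequence=_seq(iv))
        # remember the GFF ID so children can link via Derives_from
        precursors[fid]._gff_id = feat.attributes.get("ID", [feat.id])[0]  # type: ignore[attr-defined]

    gff_id_to_name = {p._gff_id: p.id for p in precursors.values()}  # type: ignore[attr-defined]

    for feat in db.features_of_type("miRNA"):
        iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        fid = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        parent_ref = feat.attributes.get("Derives_from", feat.attributes.get("Parent", [None]))[0]
        if parent_ref is None:
            raise ReferenceError(f"mature {fid}: no Derives_from/Parent attribute")
        parent = gff_id_to_name.get(parent_ref, parent_ref)
        if parent not in precursors:
            raise ReferenceError(f"mature {fid}: parent precursor {parent_ref!r} not found")
        prec = precursors[parent]
        if not prec.interval.contains(iv):
            raise ReferenceError(f"mature {fid} lies outside precursor {parent}")
        arm = _infer_arm(fid, iv, prec.interval)
        matures[fid] = MatureRecord(
            id=fid, precursor_id=parent, interval=iv, arm=arm, sequence=_seq(iv)
        )
        prec.matures.append(fid)
    return precursors, matures


_BIOTYPE_ALIASES = {
    "rrna": "rRNA", "mirna": "miRNA", "lncrna": "lncRNA", "lnc_rna": "lncRNA",
    "srp_rna": "SRP_RNA", "srprna": "SRP_RNA", "trna": "tRNA", "snorna": "snoRNA",
}


def normalize_biotype(raw: str) -> str:
    return _BIOTYPE_ALIASES.get(raw.lower(), "other")


def load_ncrna(path: str) -> list[NcRnaFeature]:
    """Load ncRNA features from GFF3 or BED (detected by extension)."""
    feats: list[NcRnaFeature] = []
    if path.endswith((".bed", ".bed.txt")):
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ReferenceError(f"{path}: malformed BED line {i}")
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"feat{i}"
                strand = parts[5] if len(parts) > 5 else "+"
                biotype = normalize_biotype(parts[6]) if len(parts) > 6 else "other"
                feats.append(
                    NcRnaFeature(name, biotype, GenomicInterval(chrom, start0 + 1, end0, strand))
                )
    else:
        db = _gff_db(path)
        for feat in db.all_features():
            biotype_raw = feat.attributes.get(
                "biotype", feat.attributes.get("type", [feat.featuretype])
            )[0]
            fid = feat.attributes.get("ID", feat.attributes.get("Name", [feat.id]))[0]
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            feats.append(
                NcRnaFeature(
                    fid,
                    normalize_biotype(biotype_raw),
                    GenomicInterval(feat.seqid, feat.start, feat.end, strand),
                )
            )
    return feats


def load_vcf(path: str) -> KnownVariantStore:
    """Load a known-SNP catalogue; only CHROM/POS/REF/ALT are used."""
    import pysam

    store = KnownVariantStore()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                store.add(rec.chrom, rec.pos, rec.ref, alt)
    return store


def load_reference(
    genome_path: str,
    mirna_gff_path: str,
    ncrna_path: str | None = None,
    vcf_path: str | None = None,
    taxon_mode: str = "animal",
) -> ReferenceBundle:
    """Load and validate all reference inputs into a :class:`ReferenceBundle`."""
    genome = _load_fasta(genome_path)
    precursors, matures = load_mirna_gff(mirna_gff_path, genome)
    ncrna = load_ncrna(ncrna_path) if ncrna_path else []
    known = None
    if vcf_path:
        if taxon_mode == "plant":
            raise ReferenceError("plant mode does not accept a known-variant catalogue")
        known = load_vcf(vcf_path)
    return ReferenceBundle(
        genome=genome,
        precursors=precursors,
        matures=matures,
        ncrna=ncrna,
        known_variants=known,
        taxon_mode=taxon_mode,
    )
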