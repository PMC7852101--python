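"""The 11-field isomiR identifier codec.

Every assigned read is encoded as eleven underscore-joined fields::

    sequence _ mature_id _ trim5 _ ext5 _ trim3 _ ext3 _
    variant_position _ variant_count _ variant_class _ tail_flag _ tail_sequence

``sequence`` is the observed transcript sequence (RNA alphabet, including any
untemplated tail).  The four numeric fields count nucleotides trimmed from /
added to each end relative to the canonical mature (an end is either trimmed
or extended, never both).  The three variant fields describe a confirmed
internal variant (position within the read in transcript orientation, number
of internal variants, classification), ``NA``/``0`` when absent.  The last two
fields flag untemplated 3' tailing (``T``/``F``) and give the tail sequence.

A canonical read therefore encodes as ``<seq>_<mir>_0_0_0_0_NA_0_NA_F_NA``.
The codec is the single source of truth for field order; ``decode(encode(x))``
is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

N_FIELDS = 11
MAX_OFFSET = 5
VARIANT_CLASSES = ("dbSNP", "A_to_I_editing", "novel_SNP", "ALT", "none")

# identifier tokens must be underscore-free to preserve the 11-field layout
_CLASS_TO_TOKEN = {
    "dbSNP": "dbSNP",
    "A_to_I_editing": "editing",
    "novel_SNP": "newSNP",
    "ALT": "ALT",
}
_TOKEN_TO_CLASS = {v: k for k, v in _CLASS_TO_TOKEN.items()}


class IdentifierError(ValueError):
    pass


@dataclass(frozen=True)
class OffsetSignature:
    """End offsets relative to the canonical mature, transcript orientation."""

    trim5: int = 0
    ext5: int = 0
    trim3: int = 0
    ext3: int = 0

    def __post_init__(self) -> None:
        for name in ("trim5", "ext5", "trim3", "ext3"):
            v = getattr(self, name)
            if not (0 <= v <= MAX_OFFSET):
                raise IdentifierError(f"{name}={v} outside 0..{MAX_OFFSET}")
        if self.trim5 and self.ext5:
            raise IdentifierError("5' end cannot be both trimmed and extended")
        if self.trim3 and self.ext3:
            raise IdentifierError("3' end cannot be both trimmed and extended")

    @property
    def is_canonical(self) -> bool:
        return not (self.trim5 or self.ext5 or self.trim3 or self.ext3)

    @property
    def total_shift(self) -> int:
        return self.trim5 + self.ext5 + self.trim3 + self.ext3


@dataclass(frozen=True)
class IsomiRIdentifier:
    """Decoded form of the 11-field identifier."""

    sequence: str
    mature_id: str
    offsets: OffsetSignature
    variant_position: int | None = None
    variant_count: int = 0
    variant_class: str = "none"
    tail_sequence: str = ""

    @property
    def tail_present(self) -> bool:
        return bool(self.tail_sequence)


def encode(ident: IsomiRIdentifier) -> str:
    """Render the 11 underscore-joined fields."""
    if "_" in ident.mature_id:
        raise IdentifierError(
            f"mature id {ident.mature_id!r} contains an underscore; "
            "it would corrupt the 11-field identifier"
        )
    if ident.variant_class not in VARIANT_CLASSES:
        raise IdentifierError(f"unknown variant class {ident.variant_class!r}")
    o = ident.offsets
    var_pos = "NA" if ident.variant_position is None else str(ident.variant_position)
    var_class = "NA" if ident.variant_class == "none" else _CLASS_TO_TOKEN[ident.variant_class]
    tail_flag = "T" if ident.tail_sequence else "F"
    tail_seq = ident.tail_sequence if ident.tail_sequence else "NA"
    fields = [
        ident.sequence,
        ident.mature_id,
        str(o.trim5),
        str(o.ext5),
        str(o.trim3),
        str(o.ext3),
        var_pos,
        str(ident.variant_count),
        var_class,
        tail_flag,
        tail_seq,
    ]
    return "_".join(fields)


def decode(id_string: str) -> IsomiRIdentifier:
    """Parse an identifier string back into its structured fields."""
    fields = id_string.split("_")
    if len(fields) != N_FIELDS:
        raise IdentifierError(
            f"expected {N_FIELDS} underscore-delimited fields, found {len(fields)}"
        )
    (seq, mature, t5, e5, t3, e3, var_pos, var_count, var_class, tail_flag, tail_seq) = fields
    try:
        offsets = OffsetSignature(int(t5), int(e5), int(t3), int(e3))
    except ValueError as exc:
        raise IdentifierError(f"bad offset fields in {id_string!r}: {exc}") from exc
    if tail_flag not in ("T", "F"):
        raise IdentifierError(f"tail flag must be T or F, got {tail_flag!r}")
    tail = "" if tail_flag == "F" else tail_seq
    if tail_flag == "T" and tail_seq == "NA":
        raise IdentifierError("tail flagged present but sequence is NA")
    if tail_flag == "F" and tail_seq != "NA":
        raise IdentifierError("tail flagged absent but a tail sequence is given")
    if var_class == "NA":
        vclass = "none"
    elif var_class in _TOKEN_TO_CLASS:
        vclass = _TOKEN_TO_CLASS[var_class]
    else:
        raise IdentifierError(f"unknown variant class token {var_class!r}")
    return IsomiRIdentifier(
        sequence=seq,
        mature_id=mature,
        offsets=offsets,
        variant_position=None if var_pos == "NA" else int(var_pos),
        variant_count=int(var_count),
        variant_class=vclass,
        tail_sequence=tail,
    )


ISOMIR_TYPES = (
    "canonical", "3p_trim", "3p_ext", "5p_trim", "5p_ext",
    "internal_variant", "tailing", "combination",
)


def isomir_type(ident: IsomiRIdentifier) -> str:
    """Single-deviation category, or ``combination`` for fuzzy isomiRs."""
    o = ident.offsets
    kinds = []
    if o.trim3:
        kinds.append("3p_trim")
    if o.ext3:
        kinds.append("3p_ext")
    if o.trim5:
        kinds.append("5p_trim")
    if o.ext5:
        kinds.append("5p_ext")
    if ident.variant_class != "none":
        kinds.append("internal_variant")
    if ident.tail_present:
        kinds.append("tailing")
    if not kinds:
        return "canonical"
    if len(kinds) == 1:
        return kinds[0]
    return "combination"
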