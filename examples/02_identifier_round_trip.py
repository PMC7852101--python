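"""Encode and decode the 11-field isomiR identifier.

The identifier packs the observed sequence, its canonical mature, the four
end offsets (trim5/ext5/trim3/ext3), the internal-variant fields and the 3'
tail fields into one underscore-joined key, so count-table rows are stable
and self-describing.
"""

from isomirkit import IsomiRIdentifier, OffsetSignature, decode, encode, isomir_type

# a 5' variant that starts one nucleotide after the canonical form and,
# being the same length, ends one nucleotide later: offsets (1,0,0,1)
ident = IsomiRIdentifier(
    sequence="AUGGCACUGGUAGAAUUCACUG",
    mature_id="hsa-miR-183-5p",
    offsets=OffsetSignature(trim5=1, ext5=0, trim3=0, ext3=1),
)
text = encode(ident)
print("encoded:", text)
print("fields :", len(text.split("_")))

back = decode(text)
print("decoded offsets:", back.offsets)
print("isomiR type    :", isomir_type(back))
assert back == ident, "decode(encode(x)) must be the identity"

# a fuzzy combination: 3' trimmed, A-to-I edited, uridylated tail
fuzzy = IsomiRIdentifier(
    sequence="AUGGCACUGGUAGAAUUCUU",
    mature_id="hsa-miR-183-5p",
    offsets=OffsetSignature(trim3=4),
    variant_position=9,
    variant_count=1,
    variant_class="A_to_I_editing",
    tail_sequence="UU",
)
print("\nfuzzy  :", encode(fuzzy))
print("type   :", isomir_type(fuzzy), "(more than one deviation kind)")
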