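"""Post-process novel-miRNA precursor candidates.

Overlapping predictions (reciprocal overlap >= 90%) are resolved toward the
higher read coverage; survivors are matched by seed (positions 2-8 of the
mature) against miRNAs known in other species.
"""

from isomirkit import GenomicInterval, NovelCandidate, match_seed_to_known, merge_overlapping

candidates = [
    NovelCandidate("cand-1", GenomicInterval("chr1", 1000, 1099, "+"), 50,
                   "UAUGGCACUGGUAGAAUUCACU"),
    NovelCandidate("cand-2", GenomicInterval("chr1", 1004, 1103, "+"), 20,
                   "UAUGGCACUGGUAGAAUUCACU"),  # 96% overlap with cand-1
    NovelCandidate("cand-3", GenomicInterval("chr1", 5000, 5099, "+"), 8,
                   "UCCCUGAGACCCUUUAACCUGU"),
]
retained = merge_overlapping(candidates, min_overlap_fraction=0.90)
print("retained after overlap merge:", [c.id for c in retained],
      "(cand-2 lost to the higher-coverage cand-1)")

foreign_seeds = {
    "AUGGCAC": ["xla-miR-183", "dre-miR-183"],
    "CCCUGAG": ["mmu-miR-125a-5p"],
}
matches = match_seed_to_known(retained, foreign_seeds)
for cid, hits in matches.items():
    print(f"{cid}: seed shared with {hits or 'no known miRNA'}")
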