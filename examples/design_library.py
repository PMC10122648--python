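"""Build the combinatorial TFBS tile library and summarize its composition.

Every tile is a 200 bp neutral background with motif kmers written in at
defined offsets and orientations (NT = kmer on the forward strand, T = its
reverse complement), with the minimal promoter at the tile's right end.
"""

import collections

import tfbsgrammar as tg

motifs = list(tg.DEFAULT_MOTIFS)
backgrounds = tg.default_backgrounds()

# Full study geometry but a compact copy set, to keep the example quick.
config = tg.LibraryConfig(
    copy_counts=(1, 2, 4),
    pair_copy_counts=(1,),
    max_full_orientation_copies=4,
    spacings=(tg.SpacingRule("fixed", 5), tg.SpacingRule("fixed", 10)),
    categories=("homotypic", "position_sweep", "pair"),
)
tiles = tg.generate_library(motifs, backgrounds, config)

by_category = collections.Counter(t.category for t in tiles)
print(f"{len(tiles)} tiles over {len(backgrounds)} backgrounds")
for cat, n in sorted(by_category.items()):
    print(f"  {cat:15s} {n:7d}")
print()
print("ordered pair permutations of 18 motifs:",
      len(tg.enumerate_permutations(motifs, 2)))
print("ordered triplet permutations:        ",
      len(tg.enumerate_permutations(motifs, 3)))
print("orientation vectors for a pair/triplet:",
      len(tg.enumerate_orientation_vectors(2)), "/",
      len(tg.enumerate_orientation_vectors(3)))

example = tiles[0]
print()
print("example tile:", example.tile_id)
print("  placements:", [(p.motif_name, p.offset, p.orientation)
                        for p in example.placements])
# Pair tiles enumerate every ordered pair in all 4 orientation vectors and
# each spacing rule; homotypic tiles sweep copy number x orientation vector.
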