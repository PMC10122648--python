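"""Simulate barcode-level MPRA counts and quantify per-tile expression.

The simulator plants a known grammar (orientation-, copy-number- and
background-dependent activity) and draws overdispersed DNA/RNA barcode
counts; quantification recovers log2(RNA/DNA) per tile and checks
replicate agreement.
"""

import numpy as np

import tfbsgrammar as tg
from tfbsgrammar.quantify import quantify, replicate_correlation
from tfbsgrammar.simulate import SimulationConfig, demo_effect_model, simulate_counts

motifs = list(tg.DEFAULT_MOTIFS)
config = tg.LibraryConfig(
    copy_counts=(1, 2, 4), max_full_orientation_copies=4,
    spacings=(tg.SpacingRule("fixed", 5),),
    categories=("homotypic", "position_sweep"),
)
tiles = tg.generate_library(motifs, tg.default_backgrounds(), config)
model = demo_effect_model(motifs, seed=0)

counts = simulate_counts(tiles, model, SimulationConfig(seed=1))
print(f"{len(tiles)} tiles, {len(counts)} barcode count rows "
      f"({counts['replicate'].nunique()} replicates)")

expr = quantify(counts, min_count=3, min_barcodes=3)
print(f"{len(expr)} tiles quantified after filtering")
print(expr[["tile_id", "rep1", "rep2", "rep3", "combined"]].head(3).to_string(index=False))

corr = replicate_correlation(expr)
off = corr.to_numpy()[np.triu_indices(3, k=1)]
print(f"replicate Pearson r: {off.round(3)} (mean {off.mean():.3f})")
# Values in the low/mid 0.7s mirror the replicate agreement typical of
# reporter libraries of this size; background 2 tiles sit systematically
# lower than background 1 (unequal baselines).
bg_means = expr.assign(bg=expr["tile_id"].str.split("|").str[1]).groupby("bg")["combined"].mean()
print("per-background mean expression:")
print(bg_means.round(3).to_string())
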