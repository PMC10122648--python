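"""Strand-aware vs strand-agnostic lasso models of tile activity.

A grammar in which six of eight motifs act antagonistically by orientation
(beta_NT = -beta_T): the strand-agnostic count model cannot see these
effects, so adding orientation to the features improves held-out
performance substantially.
"""

import tfbsgrammar as tg
from tfbsgrammar.model import compare_models, featurize, fit_lasso_cv, top_coefficients
from tfbsgrammar.quantify import quantify
from tfbsgrammar.simulate import EffectModel, SimulationConfig, simulate_counts

motifs = list(tg.DEFAULT_MOTIFS[:8])
config = tg.LibraryConfig(
    copy_counts=(1, 2, 3),
    spacings=(tg.SpacingRule("fixed", 5),),
    categories=("homotypic",),
)
tiles = tg.generate_library(motifs, tg.default_backgrounds(), config)

beta = {}
for i, m in enumerate(motifs):
    if i < 6:  # orientation-antagonistic
        beta[(m.name, tg.NT)], beta[(m.name, tg.T)] = 0.25, -0.25
    else:  # orientation-symmetric
        beta[(m.name, tg.NT)] = beta[(m.name, tg.T)] = 0.3
model = EffectModel(mu_bg={"bg1": 0.2, "bg2": -0.2}, beta=beta)

expr = quantify(simulate_counts(
    tiles, model, SimulationConfig(seed=1, barcodes_per_tile_mean=20)))
tmap = {t.tile_id: t for t in tiles}
kept = [tmap[i] for i in expr["tile_id"]]
y = expr["combined"].to_numpy()
bg_ids = [t.background_id for t in kept]
names = [m.name for m in motifs]

aware = fit_lasso_cv(featurize(kept, True, names), y, folds=10, seed=0,
                     background_ids=bg_ids)
agnostic = fit_lasso_cv(featurize(kept, False, names), y, folds=10, seed=0,
                        background_ids=bg_ids)

print(f"strand-aware   pooled r = {aware.pooled_r:.3f}")
print(f"strand-agnostic pooled r = {agnostic.pooled_r:.3f}")
print(f"improvement from orientation: {compare_models(aware, agnostic):+.1f}%")
# The improvement is the relative gain in held-out Pearson r from
# splitting each motif-count feature by orientation.

mmap = {m.name: m for m in motifs}
print("\ntop 6 coefficients (full-data strand-aware fit):")
print(top_coefficients(aware, k=6, motifs=mmap).round(3).to_string(index=False))
# Antagonistic motifs surface with opposite-sign NT and T coefficients.
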