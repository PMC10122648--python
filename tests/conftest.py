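import numpy as np
import pandas as pd
import pytest

import tfbsgrammar as tg
from tfbsgrammar.simulate import EffectModel, SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def roster():
    return list(tg.DEFAULT_MOTIFS)


@pytest.fixture(scope="session")
def backgrounds():
    return tg.default_backgrounds()


@pytest.fixture(scope="session")
def small_homotypic_library(backgrounds):
    """Homotypic tiles for six motifs, copies 1-4, one spacing."""
    cfg = tg.LibraryConfig(
        copy_counts=(1, 2, 3, 4),
        max_full_orientation_copies=4,
        spacings=(tg.SpacingRule("fixed", 5),),
        categories=("homotypic",),
    )
    return tg.generate_library(tg.DEFAULT_MOTIFS[:6], backgrounds, cfg)


@pytest.fixture(scope="session")
def toy_counts():
    """Hand-sized barcode count table covering the filter boundary cases."""
    rows = [
        # tile_a rep1: 3 barcodes at/above the DNA floor, one below
        ("tile_a", "b1", 1, 3, 50),
        ("tile_a", "b2", 1, 10, 20),
        ("tile_a", "b3", 1, 40, 40),
        ("tile_a", "b4", 1, 2, 99),
        # tile_b rep1: only 2 surviving barcodes -> dropped at min_barcodes=3
        ("tile_b", "b1", 1, 9, 9),
        ("tile_b", "b2", 1, 8, 0),
        ("tile_b", "b3", 1, 1, 7),
    ]
    return pd.DataFrame(
        rows, columns=["tile_id", "barcode_id", "replicate", "dna_count", "rna_count"]
    )


def replicated_orientation_tiles(motif, background, n_per_group, copies=1, gap=5):
    """n independent tiles per orientation group for one motif."""
    mmap = {motif.name: motif}
    tiles = []
    for orient in (tg.NT, tg.T):
        for i in range(n_per_group):
            placements = [
                tg.Placement(motif.name, 10 + j * (len(motif) + gap), orient)
                for j in range(copies)
            ]
            tiles.append(
                tg.build_tile(
                    background, placements, mmap,
                    tile_id=f"{motif.name}|{orient}|c{copies}|{i}",
                )
            )
    return tiles
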