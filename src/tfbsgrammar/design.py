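"""Combinatorial design of TFBS reporter tiles.

Builds the reporter library that the grammar analyses consume: homotypic
copy-number sweeps, single-motif position sweeps, heterotypic pair and
triplet permutations, each in every strand-orientation combination and under
three spacing rules (5 bp, 10 bp, or the modal genomic distance between the
two motifs).

Conventions (fixed throughout the package):

* Coordinates are 0-based half-open.
* Orientation ``NT`` writes the kmer on the tile's forward strand,
  ``T`` writes its reverse complement; the minimal promoter sits at the
  tile's right (3') end, so "position" of a placement is ``offset - L``
  in ``[-L, 0)`` bp relative to the TSS.
* Inter-motif distance is the spacer gap between the end of one placement
  and the start of the next; modal genomic distances are measured
  start-to-start and converted to a gap by subtracting the upstream kmer
  length (floored at 0).
* Multi-motif blocks are right-anchored (promoter-proximal) by default.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .motifs import Motif, motif_map, reverse_complement

__all__ = [
    "NT",
    "T",
    "Background",
    "Placement",
    "TileDesign",
    "SpacingRule",
    "LibraryConfig",
    "enumerate_orientation_vectors",
    "enumerate_permutations",
    "pair_distance_counts",
    "most_frequent_pair_distance",
    "build_tile",
    "generate_library",
    "default_backgrounds",
    "write_design_tsv",
    "read_design_tsv",
    "write_design_fasta",
    "region_length",
    "BACKGROUND_REGIONS",
]

logger = logging.getLogger(__name__)

NT = "NT"
T = "T"

#: hg19 regions the two neutral 200 bp backgrounds were taken from
#: (metadata; the shipped sequences are synthetic stand-ins).
BACKGROUND_REGIONS = {
    "bg1": "chr9:83712583-83712783",
    "bg2": "chr2:211153222-211153422",
}


def region_length(region: str) -> int:
    """Length in bp of a ``chrom:start-end`` region under half-open arithmetic."""
    _, coords = region.split(":")
    start, end = (int(x.replace(",", "")) for x in coords.split("-"))
    if end < start:
        raise ValueError(f"end < start in region {region!r}")
    return end - start


@dataclass(frozen=True)
class Background:
    """A neutral backbone sequence that tiles are written onto."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("background sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Placement:
    """One motif instance on a tile: (motif, 0-based offset, orientation)."""

    motif_name: str
    offset: int
    orientation: str  # NT or T

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"negative offset {self.offset}")
        if self.orientation not in (NT, T):
            raise ValueError(f"orientation must be NT or T, got {self.orientation!r}")


@dataclass(frozen=True)
class TileDesign:
    tile_id: str
    background_id: str
    category: str  # homotypic | pair | triplet | position_sweep
    placements: tuple[Placement, ...]
    sequence: str

    def motif_names(self) -> tuple[str, ...]:
        return tuple(p.motif_name for p in self.placements)

    def orientations(self) -> tuple[str, ...]:
        return tuple(p.orientation for p in self.placements)


@dataclass(frozen=True)
class SpacingRule:
    """Gap rule between adjacent motifs: fixed bp or modal genomic distance."""

    kind: str  # "fixed" | "genomic_mode"
    value: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "genomic_mode"):
            raise ValueError(f"unknown spacing kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("spacing value must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.value}" if self.kind == "fixed" else "genomic"


def enumerate_orientation_vectors(n: int) -> list[tuple[str, ...]]:
    """All 2**n orientation vectors over {NT, T}, lexicographic (NT < T)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return list(itertools.product((NT, T), repeat=n))


def enumerate_permutations(
    motifs: Sequence[Motif], k: int
) -> list[tuple[Motif, ...]]:
    """All ordered k-tuples of distinct motifs, in stable roster order."""
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        dupes = [n for n, c in Counter(names).items() if c > 1]
        raise ValueError(f"duplicate motif names: {dupes}")
    if k > len(motifs):
        raise ValueError(f"k={k} exceeds roster size {len(motifs)}")
    return list(itertools.permutations(motifs, k))


def pair_distance_counts(
    positions_a: Sequence[int], positions_b: Sequence[int], max_gap: int
) -> Counter:
    """Histogram of |start-to-start| distances in (0, max_gap]."""
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    counts: Counter = Counter()
    for a in positions_a:
        for b in positions_b:
            d = abs(b - a)
            if 0 < d <= max_gap:
                counts[d] += 1
    return counts


#: gap used when no occurrence pair falls inside the search window
DEFAULT_FALLBACK_DISTANCE = 10


def most_frequent_pair_distance(
    positions_a: Sequence[int],
    positions_b: Sequence[int],
    max_gap: int = 200,
) -> tuple[int, bool]:
    """Modal start-to-start distance between two occurrence lists.

    Returns ``(distance, fallback_used)``.  Ties break toward the smallest
    distance; when no pair lies within ``(0, max_gap]`` (including empty
    inputs) the documented default of 10 bp is returned with the fallback
    flag set.
    """
    counts = pair_distance_counts(positions_a, positions_b, max_gap)
    if not counts:
        return DEFAULT_FALLBACK_DISTANCE, True
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0], False


def build_tile(
    background: Background,
    placements: Sequence[Placement],
    motifs: Mapping[str, Motif],
    tile_id: str = "",
    category: str = "homotypic",
) -> TileDesign:
    """Write placements onto a background sequence.

    Each placement window is overwritten by the motif kmer (NT) or its
    reverse complement (T).  Placements must be sorted by offset,
    non-overlapping and in-bounds.
    """
    seq = list(background.sequence)
    prev_end = -1
    prev: Placement | None = None
    for p in sorted(placements, key=lambda p: p.offset):
        if p.motif_name not in motifs:
            raise KeyError(f"unknown motif {p.motif_name!r}")
        kmer = motifs[p.motif_name].kmer
        end = p.offset + len(kmer)
        if end > background.length:
            raise ValueError(
                f"placement {p.motif_name}@{p.offset} extends past tile end "
                f"({end} > {background.length})"
            )
        if p.offset < prev_end:
            raise ValueError(
                f"overlapping placements: {prev.motif_name}@{prev.offset} and "
                f"{p.motif_name}@{p.offset}"
            )
        ins = kmer if p.orientation == NT else reverse_complement(kmer)
        seq[p.offset : end] = ins
        prev_end, prev = end, p
    return TileDesign(
        tile_id=tile_id,
        background_id=background.id,
        category=category,
        placements=tuple(sorted(placements, key=lambda p: p.offset)),
        sequence="".join(seq),
    )


@dataclass(frozen=True)
class LibraryConfig:
    """Knobs for :func:`generate_library`.

    Defaults follow the study design: homotypic copies {1,2,3,4,5,6,8},
    pair member copies {1,2,3}, spacings 5 bp / 10 bp / genomic mode,
    triplets at genomic-mode spacing only, 40 bp position-sweep bins,
    right-anchored blocks.  Homotypic orientation vectors are fully
    enumerated up to 6 copies; for 8 copies only all-NT, all-T and the two
    alternating vectors are emitted (library-size control).
    """

    copy_counts: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8)
    pair_copy_counts: tuple[int, ...] = (1, 2, 3)
    spacings: tuple[SpacingRule, ...] = (
        SpacingRule("fixed", 5),
        SpacingRule("fixed", 10),
        SpacingRule("genomic_mode"),
    )
    triplet_spacings: tuple[SpacingRule, ...] = (SpacingRule("genomic_mode"),)
    position_bin_width: int = 40
    max_full_orientation_copies: int = 6
    anchor: str = "right"  # right | left | center
    categories: tuple[str, ...] = ("homotypic", "position_sweep", "pair", "triplet")
    genomic_gaps: Mapping[tuple[str, str], int] = field(default_factory=dict)


def _resolve_gap(
    rule: SpacingRule, pair: tuple[str, str], config: LibraryConfig
) -> int:
    if rule.kind == "fixed":
        return rule.value
    return config.genomic_gaps.get(pair, DEFAULT_FALLBACK_DISTANCE)


def _layout_offsets(
    kmer_lengths: Sequence[int], gaps: Sequence[int], tile_length: int, anchor: str
) -> list[int]:
    block = sum(kmer_lengths) + sum(gaps)
    if block > tile_length:
        raise ValueError(f"block of {block} bp does not fit in {tile_length} bp tile")
    if anchor == "right":
        start = tile_length - block
    elif anchor == "left":
        start = 0
    elif anchor == "center":
        start = (tile_length - block) // 2
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    offsets = []
    pos = start
    for i, L in enumerate(kmer_lengths):
        offsets.append(pos)
        pos += L + (gaps[i] if i < len(gaps) else 0)
    return offsets


def _homotypic_vectors(n: int, max_full: int) -> list[tuple[str, ...]]:
    if n <= max_full:
        return enumerate_orientation_vectors(n)
    alternating = tuple((NT, T)[i % 2] for i in range(n))
    return [
        (NT,) * n,
        (T,) * n,
        alternating,
        tuple(T if o == NT else NT for o in alternating),
    ]


def _block_tile(
    background: Background,
    motif_seq: Sequence[Motif],
    orientations: Sequence[str],
    gap: int,
    config: LibraryConfig,
    motifs: Mapping[str, Motif],
    tile_id: str,
    category: str,
) -> TileDesign:
    lens = [len(m) for m in motif_seq]
    gaps = [gap] * (len(motif_seq) - 1)
    offsets = _layout_offsets(lens, gaps, background.length, config.anchor)
    placements = [
        Placement(m.name, off, o)
        for m, off, o in zip(motif_seq, offsets, orientations)
    ]
    return build_tile(background, placements, motifs, tile_id, category)


def generate_library(
    motifs: Sequence[Motif],
    backgrounds: Sequence[Background],
    config: LibraryConfig | None = None,
) -> list[TileDesign]:
    """Enumerate the full combinatorial tile library.

    Emits, per background: homotypic tiles (motif x copy count x orientation
    vector x spacing rule), single-motif position-sweep tiles across 40 bp
    bins in both orientations, pair tiles (all ordered pairs x 4 orientation
    vectors x spacing rules x member copy counts) and triplet tiles (all
    ordered triplets x 8 orientation vectors at genomic-mode spacing).
    Configurations whose block does not fit the tile are skipped and logged.
    Tile ids are unique and deterministic, so identical configs yield
    byte-identical design tables.
    """
    config = config or LibraryConfig()
    mmap = motif_map(motifs)
    tiles: list[TileDesign] = []
    skipped = 0

    def emit(bg, motif_seq, orients, gap, spacing_label, category, tag):
        nonlocal skipped
        tile_id = (
            f"{category}|{bg.id}|{'-'.join(m.name for m in motif_seq)}"
            f"|{''.join('n' if o == NT else 't' for o in orients)}"
            f"|s{spacing_label}|{tag}"
        )
        try:
            tiles.append(
                _block_tile(bg, motif_seq, orients, gap, config, mmap, tile_id, category)
            )
        except ValueError:
            skipped += 1
            logger.debug("skipped (does not fit): %s", tile_id)

    for bg in backgrounds:
        if "homotypic" in config.categories:
            for m in motifs:
                for c in config.copy_counts:
                    vecs = _homotypic_vectors(c, config.max_full_orientation_copies)
                    rules = config.spacings if c > 1 else (SpacingRule("fixed", 0),)
                    for rule in rules:
                        gap = _resolve_gap(rule, (m.name, m.name), config)
                        label = rule.label if c > 1 else "-"
                        for vec in vecs:
                            emit(bg, (m,) * c, vec, gap, label, "homotypic", f"c{c}")

        if "position_sweep" in config.categories:
            w = config.position_bin_width
            for m in motifs:
                for bin_lo in range(-bg.length, 0, w):
                    offset = bg.length + bin_lo
                    if offset + len(m) > bg.length:
                        offset = bg.length - len(m)
                    for o in (NT, T):
                        tile_id = (
                            f"position_sweep|{bg.id}|{m.name}"
                            f"|{'n' if o == NT else 't'}|s-|p{bin_lo}"
                        )
                        tiles.append(
                            build_tile(
                                bg,
                                [Placement(m.name, offset, o)],
                                mmap,
                                tile_id,
                                "position_sweep",
                            )
                        )

        if "pair" in config.categories:
            for a, b in enumerate_permutations(motifs, 2):
                for c in config.pair_copy_counts:
                    for rule in config.spacings:
                        gap = _resolve_gap(rule, (a.name, b.name), config)
                        for oa, ob in enumerate_orientation_vectors(2):
                            motif_seq = (a,) * c + (b,) * c
                            orients = (oa,) * c + (ob,) * c
                            emit(
                                bg, motif_seq, orients, gap, rule.label,
                                "pair", f"c{c}",
                            )

        if "triplet" in config.categories:
            for trip in enumerate_permutations(motifs, 3):
                for rule in config.triplet_spacings:
                    gap = _resolve_gap(rule, (trip[0].name, trip[1].name), config)
                    for vec in enumerate_orientation_vectors(3):
                        emit(bg, trip, vec, gap, rule.label, "triplet", "c1")

    if skipped:
        logger.info("generate_library: skipped %d non-fitting configurations", skipped)
    ids = [t.tile_id for t in tiles]
    if len(set(ids)) != len(ids):
        raise AssertionError("non-unique tile ids generated")
    return tiles


def default_backgrounds(length: int = 200) -> list[Background]:
    """Two deterministic synthetic neutral backgrounds.

    Stand-ins for the study's two 200 bp neutral genomic sequences (hg19
    regions recorded in :data:`BACKGROUND_REGIONS`); generated from a fixed
    linear congruential stream so they are identical across runs and
    platforms.
    """
    seqs = []
    state = 2023
    for _ in range(2):
        chars = []
        for _ in range(length):
            state = (1103515245 * state + 12345) % (2**31)
            chars.append("ACGT"[state % 4])
        seqs.append("".join(chars))
    return [Background("bg1", seqs[0]), Background("bg2", seqs[1])]


def design_frame(tiles: Sequence[TileDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tile_id": [t.tile_id for t in tiles],
            "background_id": [t.background_id for t in tiles],
            "category": [t.category for t in tiles],
            "motif_names": [",".join(t.motif_names()) for t in tiles],
            "orientations": [",".join(t.orientations()) for t in tiles],
            "offsets": [",".join(str(p.offset) for p in t.placements) for t in tiles],
            "sequence": [t.sequence for t in tiles],
        }
    )


def write_design_tsv(tiles: Sequence[TileDesign], path: str | Path) -> None:
    design_frame(tiles).to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> list[TileDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    tiles = []
    for r in df.to_dict("records"):
        names = r["motif_names"].split(",") if r["motif_names"] else []
        orients = r["orientations"].split(",") if r["orientations"] else []
        offsets = [int(x) for x in r["offsets"].split(",")] if r["offsets"] else []
        placements = tuple(
            Placement(n, off, o) for n, off, o in zip(names, offsets, orients)
        )
        tiles.append(
            TileDesign(
                r["tile_id"], r["background_id"], r["category"], placements,
                r["sequence"],
            )
        )
    return tiles


def write_design_fasta(tiles: Sequence[TileDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tiles:
            fh.write(f">{t.tile_id}\n{t.sequence}\n")
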