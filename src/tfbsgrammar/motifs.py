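"""Transcription factor binding site (TFBS) motifs as fixed kmers.

Each transcription factor is represented by a single kmer with orientation
semantics: a binding site can sit on the *non-template* strand (NT; the kmer
as written on the strand transcribed 5'->3' toward the reporter's minimal
promoter) or on the *template* strand (T; its reverse complement as written
on that strand).  Palindromic kmers cannot be oriented and serve as
orientation-negative controls.

The default roster covers eleven liver regulators and seven general factors.
AP1 ("TGACTCA") and CREB1 ("TGACGTCA", the single palindrome) carry their
documented kmers; the remaining sixteen kmers are synthetic consensus-style
stand-ins chosen to be non-palindromic, with JASPAR/HOCOMOCO accessions
attached as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Motif",
    "reverse_complement",
    "is_palindromic",
    "gc_skew",
    "at_skew",
    "DEFAULT_MOTIFS",
    "read_motif_tsv",
    "write_motif_tsv",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def _validate_dna(seq: str) -> None:
    for i, base in enumerate(seq):
        if base not in _VALID:
            raise ValueError(
                f"invalid DNA character {base!r} at position {i} (ACGT only)"
            )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string.

    Raises ``ValueError`` naming the first offending position for non-ACGT
    input.  Applying the function twice returns the input (involution).
    """
    _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindromic(kmer: str) -> bool:
    """True iff the kmer equals its own reverse complement."""
    return kmer == reverse_complement(kmer)


def gc_skew(kmer: str) -> float:
    """(G - C) / (G + C) of the kmer; 0.0 when it has no G or C."""
    _validate_dna(kmer)
    g, c = kmer.count("G"), kmer.count("C")
    return 0.0 if g + c == 0 else (g - c) / (g + c)


def at_skew(kmer: str) -> float:
    """(A - T) / (A + T) of the kmer; 0.0 when it has no A or T."""
    _validate_dna(kmer)
    a, t = kmer.count("A"), kmer.count("T")
    return 0.0 if a + t == 0 else (a - t) / (a + t)


@dataclass(frozen=True)
class Motif:
    """A named TFBS kmer.

    Attributes
    ----------
    name : str
        Transcription factor name (unique within a roster).
    kmer : str
        The binding-site kmer, uppercase ACGT, written in the non-template
        orientation.
    source_id : str
        Database accession (e.g. a JASPAR matrix ID); metadata only.
    """

    name: str
    kmer: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.kmer:
            raise ValueError("kmer must be non-empty")
        _validate_dna(self.kmer)

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.kmer)

    def __len__(self) -> int:
        return len(self.kmer)


# AP1 and CREB1 kmers are the documented ones; all other kmers are synthetic
# consensus-style stand-ins (non-palindromic by construction).  Accessions
# are metadata only.
DEFAULT_MOTIFS: tuple[Motif, ...] = (
    Motif("AHR", "TTGCGTGA", "AHR_HUMAN.H11MO.0"),
    Motif("AP1", "TGACTCA", "MA0099"),
    Motif("CEBPA", "TTGCACAA", "MA0102.3"),
    Motif("CREB1", "TGACGTCA", "MA0018"),
    Motif("CTCF", "CCACCAGGGGG", "MA0139.1"),
    Motif("FOXA1", "TGTTTACTT", "MA0148.3"),
    Motif("GABPA", "ACCGGAAGT", "MA0062.2"),
    Motif("HNF1A", "GTTAATCATTAA", "MA0046.2"),
    Motif("HNF4A", "GGTCAAAGGTCA", "MA0114.3"),
    Motif("NR2F2", "GGGTCAAAGGTC", "MA1111.1"),
    Motif("ONECUT1", "TATTGATTT", "MA0679.1"),
    Motif("PPARA", "TGACCTTTGCCC", "MA1148.1"),
    Motif("REST", "TTCAGCACCACG", "MA0138.2"),
    Motif("RXRA", "GGGTCAAGGGTC", "MA0512.2"),
    Motif("SP1", "GGGGCGGGG", "MA0079.3"),
    Motif("TFAP2C", "GCCTGAGGC", "MA0524.2"),
    Motif("XBP1", "TGACGTGG", "MA0844.1"),
    Motif("YY1", "AAATGGCG", "MA0095.2"),
)


def motif_map(motifs: Iterable[Motif]) -> dict[str, Motif]:
    """Name -> Motif mapping; rejects duplicate names."""
    out: dict[str, Motif] = {}
    for m in motifs:
        if m.name in out:
            raise ValueError(f"duplicate motif name {m.name!r}")
        out[m.name] = m
    return out


def read_motif_tsv(path: str | Path) -> list[Motif]:
    """Read a motif roster TSV with columns name, kmer[, source_id]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "source_id" not in df.columns:
        df["source_id"] = ""
    return [
        Motif(r["name"], r["kmer"], r.get("source_id", "") or "")
        for r in df.to_dict("records")
    ]


def write_motif_tsv(motifs: Iterable[Motif], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": m.name, "kmer": m.kmer, "source_id": m.source_id} for m in motifs]
    ).to_csv(path, sep="\t", index=False)
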