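"""Genomic corroboration analyses.

PWM scanning with an exact p-value score threshold, promoter extraction,
strand-asymmetry and order-preference binomial statistics on motif
occurrences, an exact dinucleotide-preserving shuffle for null sequences,
candidate cis-regulatory element (cCRE) pair enrichment, and pair-distance
histograms.

Occurrences travel as BED6-style DataFrames
(chrom, start, end, name, score, strand; 0-based half-open).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binomtest

from .design import pair_distance_counts
from .motifs import reverse_complement
from .stats import bonferroni_adjust

__all__ = [
    "PWM",
    "pfm_to_pwm",
    "score_distribution",
    "score_threshold",
    "scan_sequence",
    "read_meme_pfms",
    "extract_promoters",
    "PromoterRecord",
    "consecutive_homotypic_asymmetry",
    "pair_order_preference",
    "dinucleotide_shuffle",
    "ccre_pair_enrichment",
    "pair_distance_histogram",
    "read_bed",
    "write_bed",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PWM:
    """Log-odds position weight matrix over A, C, G, T."""

    name: str
    matrix: np.ndarray  # (width, 4) log2 odds
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("matrix must be (width >= 1, 4)")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        # complement of base code b is 3 - b; reverse positions too
        return PWM(self.name, self.matrix[::-1, ::-1], self.background, self.threshold)


def pfm_to_pwm(
    pfm,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.01,
    name: str = "",
) -> PWM:
    """Count matrix -> log2-odds PWM.

    ``score[i, b] = log2(((count + pc * bg_b) / (colsum + pc)) / bg_b)``.
    """
    counts = np.asarray(pfm, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("PFM must be (width, 4)")
    if (counts < 0).any():
        raise ValueError("PFM counts must be non-negative")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    colsum = counts.sum(axis=1, keepdims=True)
    if pseudocount <= 0 and (colsum == 0).any():
        raise ValueError("zero-sum PFM column requires a positive pseudocount")
    probs = (counts + pseudocount * bg) / (colsum + pseudocount)
    return PWM(name, np.log2(probs / bg), bg)


def score_distribution(pwm: PWM, precision: float = 1e-3) -> tuple[int, np.ndarray]:
    """Exact pmf of the window score under the background model.

    Scores are quantized to multiples of ``precision``; the pmf is built by
    position-wise convolution of the per-column score distributions.
    Returns ``(lowest_integer_score, pmf)`` where entry ``i`` is the
    probability of integer score ``lowest + i``.
    """
    scores = np.rint(pwm.matrix / precision).astype(np.int64)
    pmf = np.array([1.0])
    lo = 0
    for row, _ in zip(scores, range(pwm.width)):
        rmin, rmax = int(row.min()), int(row.max())
        new = np.zeros(pmf.size + (rmax - rmin))
        for base in range(4):
            shift = int(row[base]) - rmin
            new[shift : shift + pmf.size] += pwm.background[base] * pmf
        pmf, lo = new, lo + rmin
    return lo, pmf


def score_threshold(
    pwm: PWM, p_value: float = 1e-4, precision: float = 1e-3
) -> tuple[float, bool]:
    """Smallest score with background tail probability <= p_value.

    Exact dynamic program over the quantized score distribution.  Returns
    ``(threshold, capped)``; ``capped`` is True when even the maximum
    score is more probable than ``p_value`` (threshold then equals the
    maximum score).  The threshold is stored on the PWM as a side effect.
    """
    if not 0 < p_value < 1:
        raise ValueError("p_value must be in (0, 1)")
    lo, pmf = score_distribution(pwm, precision)
    tail = np.cumsum(pmf[::-1])[::-1]  # tail[i] = P(score >= lo + i)
    achievable = pmf > 0
    ok = achievable & (tail <= p_value)
    if ok.any():
        idx = int(np.argmax(ok))
        threshold, capped = (lo + idx) * precision, False
    else:
        idx = int(np.max(np.flatnonzero(achievable)))
        threshold, capped = (lo + idx) * precision, True
        logger.warning(
            "score_threshold(%s): p=%g below best-score probability; "
            "threshold capped at max score", pwm.name, p_value,
        )
    pwm.threshold = threshold
    return threshold, capped


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, -1) for b in seq.upper()), dtype=np.int64,
                       count=len(seq))


def _strand_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    w = matrix.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(windows.shape[0], -np.inf)
    if valid.any():
        vw = windows[valid]
        scores[valid] = matrix[np.arange(w)[None, :], vw].sum(axis=1)
    return scores


def scan_sequence(seq: str, pwm: PWM, seq_id: str = "seq") -> pd.DataFrame:
    """Score every window on both strands; report hits >= pwm.threshold.

    Minus-strand hits carry forward-strand coordinates.  Windows containing
    non-ACGT characters are skipped; a threshold must have been set (via
    :func:`score_threshold` or directly).
    """
    if pwm.threshold is None:
        raise ValueError("PWM has no threshold; call score_threshold first")
    w = pwm.width
    if len(seq) < w:
        return read_bed(None)
    codes = _encode(seq)
    rows = []
    for strand, matrix in (("+", pwm.matrix), ("-", pwm.reverse_complement().matrix)):
        scores = _strand_scores(codes, matrix)
        for pos in np.flatnonzero(scores >= pwm.threshold):
            rows.append((seq_id, int(pos), int(pos) + w, pwm.name,
                         float(scores[pos]), strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return df.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def read_meme_pfms(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Parse a minimal-MEME motif file into (name, count-matrix) pairs."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)],
                          dtype=float)
        out.append((m.name, counts))
    return out


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open genomic interval of the promoter
    end: int
    strand: str
    sequence: str  # read 5'->3' toward the TSS
    truncated: bool = False


def extract_promoters(
    gtf_path: str | Path, fasta_path: str | Path, upstream: int = 2500
) -> list[PromoterRecord]:
    """Promoters as the ``upstream`` bp 5' of each gene's TSS, strand-aware.

    '+' genes yield ``[start - upstream, start)``; '-' genes yield
    ``[end, end + upstream)`` reverse-complemented so every promoter reads
    toward the TSS.  Intervals are truncated at contig edges (flagged);
    genes on contigs missing from the FASTA are skipped with a warning.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gtf_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    fasta = Fasta(str(fasta_path))
    out = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in fasta:
            logger.warning("extract_promoters: contig %s not in FASTA; skipping %s",
                           gene.seqid, gene.id)
            continue
        contig_len = len(fasta[gene.seqid])
        if gene.strand == "-":
            lo = gene.end  # 0-based start of downstream flank
            hi = min(contig_len, gene.end + upstream)
            seq = reverse_complement(str(fasta[gene.seqid][lo:hi]).upper())
            truncated = hi - lo < upstream
        else:
            tss0 = gene.start - 1
            lo = max(0, tss0 - upstream)
            hi = tss0
            seq = str(fasta[gene.seqid][lo:hi]).upper()
            truncated = hi - lo < upstream
        out.append(PromoterRecord(gene.id, gene.seqid, lo, hi,
                                  gene.strand or "+", seq, truncated))
    return out


def _merge_overlaps(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping same-motif occurrences to the higher-scoring one."""
    keep = []
    for _, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        current = None
        for row in grp.itertuples():
            if current is not None and row.start < current.end:
                if row.score > current.score:
                    current = row
            else:
                if current is not None:
                    keep.append(current)
                current = row
        if current is not None:
            keep.append(current)
    return pd.DataFrame(keep).drop(columns=["Index"], errors="ignore")


def consecutive_homotypic_asymmetry(
    occurrences: pd.DataFrame,
    max_gap: int = 100,
    merge_overlaps: bool = True,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Strand asymmetry S of consecutive same-motif occurrence pairs.

    For each motif, adjacent occurrences on the same sequence whose
    edge-to-edge gap is in [0, max_gap) are classified same- vs
    opposite-strand; S = n_same / (n_same + n_opposite), tested against 0.5
    with a two-sided exact binomial test, Bonferroni over motifs with at
    least one eligible pair.
    """
    rows = []
    for motif, occ in occurrences.groupby("name"):
        if merge_overlaps and "score" in occ.columns:
            occ = _merge_overlaps(occ)
        n_same = n_opp = 0
        for _, grp in occ.groupby("chrom"):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            strands = grp["strand"].to_numpy()
            gaps = starts[1:] - ends[:-1]
            eligible = (gaps >= 0) & (gaps < max_gap)
            same = strands[1:] == strands[:-1]
            n_same += int((eligible & same).sum())
            n_opp += int((eligible & ~same).sum())
        n = n_same + n_opp
        if n < 1:
            logger.info("asymmetry: motif %s has no eligible pairs; excluded", motif)
            continue
        p = binomtest(n_same, n, 0.5, alternative="two-sided").pvalue
        rows.append((motif, n_same, n_opp, n_same / n, p))
    out = pd.DataFrame(rows, columns=["motif", "n_same", "n_opposite", "S", "p_raw"])
    m = m_tests if m_tests is not None else max(len(out), 1)
    out["p_adjusted"] = bonferroni_adjust(out["p_raw"].to_numpy(), m) if len(out) else []
    return out


def pair_order_preference(
    occurrences: pd.DataFrame,
    tss_positions: Mapping[str, int],
    window: int = 100,
    pairs: Sequence[tuple[str, str]] | None = None,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Binomial test of TSS-proximal preference for each motif pair.

    For every co-occurrence of motifs A and B on the same sequence within
    ``window`` bp (start-to-start), records whether A or B lies closer to
    that sequence's TSS; tests the A-proximal fraction against 0.5.
    """
    by_chrom: dict[str, pd.DataFrame] = dict(tuple(occurrences.groupby("chrom")))
    names = sorted(occurrences["name"].unique())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        n_a_prox = n = 0
        for chrom, occ in by_chrom.items():
            if chrom not in tss_positions:
                continue
            tss = tss_positions[chrom]
            occ_a = occ.loc[occ["name"] == a, "start"].to_numpy()
            occ_b = occ.loc[occ["name"] == b, "start"].to_numpy()
            for sa in occ_a:
                for sb in occ_b:
                    if abs(int(sa) - int(sb)) > window:
                        continue
                    da, db_ = abs(tss - int(sa)), abs(tss - int(sb))
                    if da == db_:
                        continue
                    n += 1
                    n_a_prox += int(da < db_)
        if n < 1:
            continue
        p = binomtest(n_a_prox, n, 0.5, alternative="two-sided").pvalue
        rows.append((a, b, n, n_a_prox, n_a_prox / n, p))
    out = pd.DataFrame(
        rows, columns=["motif_a", "motif_b", "n", "n_a_proximal",
                       "frac_a_proximal", "p_raw"]
    )
    m = m_tests if m_tests is not None else max(len(out), 1)
    out["p_adjusted"] = bonferroni_adjust(out["p_raw"].to_numpy(), m) if len(out) else []
    return out


def dinucleotide_shuffle(seq: str, seed: int | None = None,
                         rng: np.random.Generator | None = None) -> str:
    """Uniform random shuffle preserving the exact dinucleotide multiset.

    Altschul-Erickson Euler-path construction: pick random "last" edges
    forming a tree into the terminal character, shuffle the remaining edges,
    and walk the resulting Eulerian path.  Mononucleotide counts and the
    first and last characters are preserved as a consequence.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    non_terminal = [v for v in edges if v != last]
    while True:
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in non_terminal}
        if all(_reaches(v, last, last_edge) for v in non_terminal):
            break
    out_lists: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        rest = [rest[i] for i in perm]
        if v in last_edge:
            rest.append(last_edge[v])
        out_lists[v] = rest
    walk = [seq[0]]
    ptr = {v: 0 for v in out_lists}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = out_lists[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def _reaches(v: str, target: str, last_edge: Mapping[str, str]) -> bool:
    seen = set()
    while v != target:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


def ccre_pair_enrichment(
    occurrences: pd.DataFrame,
    elements: pd.DataFrame,
    pair_window: int = 100,
) -> pd.DataFrame:
    """Fraction of close TFBS pairs overlapping each element class.

    A "pair" is two occurrences of different motifs on the same sequence
    within ``pair_window`` bp start-to-start; its footprint is the interval
    spanning both occurrences.  For each motif pair and element class the
    reported fraction is (pairs overlapping that class) / (all close pairs
    of that motif pair); pairs overlapping no element are allowed, so rows
    sum to <= 1 when classes are disjoint.
    """
    if elements.empty:
        raise ValueError("element set is empty")
    classes = sorted(elements["label"].unique())
    trees: dict[tuple[str, str], IntervalTree] = {}
    for (chrom, label), grp in elements.groupby(["chrom", "label"]):
        trees[(chrom, label)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
        )
    counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    totals: Counter = Counter()
    for chrom, occ in occurrences.groupby("chrom"):
        occ = occ.sort_values("start")
        recs = list(occ[["start", "end", "name"]].itertuples(index=False))
        for i, r1 in enumerate(recs):
            for r2 in recs[i + 1:]:
                if r2.start - r1.start > pair_window:
                    break
                if r1.name == r2.name:
                    continue
                key = tuple(sorted((r1.name, r2.name)))
                totals[key] += 1
                lo, hi = min(r1.start, r2.start), max(r1.end, r2.end)
                for label in classes:
                    tree = trees.get((chrom, label))
                    if tree is not None and tree.overlap(lo, hi):
                        counts[key][label] += 1
    rows = []
    for key, n in sorted(totals.items()):
        row = {"motif_a": key[0], "motif_b": key[1], "n_pairs": n}
        for label in classes:
            row[label] = counts[key][label] / n
        rows.append(row)
    return pd.DataFrame(rows)


def pair_distance_histogram(
    starts_a: Sequence[int], starts_b: Sequence[int], max_gap: int = 200
) -> dict[int, int]:
    """Histogram of |start-to-start| distances in (0, max_gap]."""
    return dict(sorted(pair_distance_counts(starts_a, starts_b, max_gap).items()))


def read_bed(path: str | Path | None) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    if path is None:
        return pd.DataFrame(columns=cols)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
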