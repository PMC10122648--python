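import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfbsgrammar.motifs import reverse_complement
from tfbsgrammar.scan import (
    PWM,
    ccre_pair_enrichment,
    consecutive_homotypic_asymmetry,
    dinucleotide_shuffle,
    extract_promoters,
    pair_distance_histogram,
    pair_order_preference,
    pfm_to_pwm,
    read_meme_pfms,
    scan_sequence,
    score_distribution,
    score_threshold,
)

CODE = {b: i for i, b in enumerate("ACGT")}


def consensus_pfm(consensus, weight=10.0):
    pfm = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        pfm[i, CODE[b]] = weight
    return pfm


def brute_force_threshold(pwm, p_value, precision=1e-3):
    """Oracle: enumerate all 4^w windows on the quantized score grid."""
    q = np.rint(pwm.matrix / precision).astype(int)
    w = pwm.width
    scores, probs = [], []
    for word in itertools.product(range(4), repeat=w):
        scores.append(q[np.arange(w), word].sum())
        probs.append(np.prod(pwm.background[list(word)]))
    scores, probs = np.array(scores), np.array(probs)
    best = None
    for s in np.unique(scores):
        if probs[scores >= s].sum() <= p_value:
            best = s
            break
    capped = best is None
    if capped:
        best = scores.max()
    return best * precision, capped


class TestPfmToPwm:
    def test_uniform_pfm_uniform_background_all_zero(self):
        pwm = pfm_to_pwm(np.full((4, 4), 5.0))
        assert np.allclose(pwm.matrix, 0.0, atol=1e-3)

    def test_single_base_column_near_log2_4(self):
        pfm = np.zeros((1, 4))
        pfm[0, 0] = 100.0
        pwm = pfm_to_pwm(pfm, pseudocount=0.01)
        assert pwm.matrix[0, 0] == pytest.approx(2.0, abs=0.01)

    def test_background_matching_column_scores_zero(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        pfm = np.array([[40.0, 10.0, 10.0, 40.0]])
        pwm = pfm_to_pwm(pfm, background=bg, pseudocount=1e-9)
        assert np.allclose(pwm.matrix, 0.0, atol=1e-6)

    def test_zero_column_needs_pseudocount(self):
        with pytest.raises(ValueError):
            pfm_to_pwm(np.zeros((2, 4)), pseudocount=0.0)


class TestScoreThreshold:
    @pytest.mark.parametrize("width", [1, 2, 3, 5, 8])
    def test_dp_matches_brute_force(self, width):
        rng = np.random.default_rng(width)
        pfm = rng.integers(0, 25, (width, 4)).astype(float)
        pwm = pfm_to_pwm(pfm, pseudocount=0.5)
        p = 0.25 if width <= 2 else 1e-3
        thr, capped = score_threshold(pwm, p)
        bf_thr, bf_capped = brute_force_threshold(pwm, p)
        assert capped == bf_capped
        assert thr == pytest.approx(bf_thr, abs=1e-9)

    def test_width1_quartile_threshold(self):
        # uniform background, p=0.25 -> only the single best base passes
        pfm = np.array([[10.0, 5.0, 2.0, 1.0]])
        pwm = pfm_to_pwm(pfm, pseudocount=0.1)
        thr, capped = score_threshold(pwm, 0.25)
        assert not capped
        assert thr == pytest.approx(np.rint(pwm.matrix.max() / 1e-3) * 1e-3)

    def test_near_one_p_admits_almost_all_windows(self):
        pfm = np.array([[5.0, 1.0, 1.0, 1.0], [1.0, 5.0, 1.0, 1.0]])
        pwm = pfm_to_pwm(pfm, pseudocount=0.1)
        thr, capped = score_threshold(pwm, 0.999999)
        lo, pmf = score_distribution(pwm)
        achievable = np.flatnonzero(pmf > 0)
        # tail at the minimum is exactly 1 > p, so the threshold is the
        # second-smallest achievable score
        assert not capped
        assert thr == pytest.approx((lo + int(achievable[1])) * 1e-3)

    def test_tiny_p_caps_at_max_score(self):
        pwm = pfm_to_pwm(consensus_pfm("ACG"), pseudocount=0.1)
        thr, capped = score_threshold(pwm, 1e-9)
        assert capped

    def test_distribution_sums_to_one(self):
        pwm = pfm_to_pwm(np.random.default_rng(0).integers(1, 9, (6, 4)).astype(float))
        _, pmf = score_distribution(pwm)
        assert pmf.sum() == pytest.approx(1.0)


class TestScanSequence:
    def _pwm(self, consensus):
        pwm = pfm_to_pwm(consensus_pfm(consensus), pseudocount=0.1, name="M")
        score_threshold(pwm, 1e-3)
        return pwm

    def test_planted_consensus_found_forward(self):
        pwm = self._pwm("TGACGT")
        hits = scan_sequence("A" * 20 + "TGACGT" + "A" * 20, pwm)
        fwd = hits[hits.strand == "+"]
        assert list(fwd["start"]) == [20]
        assert list(fwd["end"]) == [26]

    def test_planted_reverse_complement_found_on_minus(self):
        pwm = self._pwm("TGACGT")
        seq = "C" * 20 + reverse_complement("TGACGT") + "C" * 20
        hits = scan_sequence(seq, pwm)
        assert list(hits["strand"]) == ["-"]
        assert list(hits["start"]) == [20]  # forward-strand interval

    def test_windows_with_n_skipped(self):
        pwm = self._pwm("TGACGT")
        hits = scan_sequence("A" * 5 + "TGANGT" + "A" * 5, pwm)
        assert hits.empty

    def test_short_sequence_empty(self):
        pwm = self._pwm("TGACGT")
        assert scan_sequence("TGA", pwm).empty

    def test_equivalence_with_brute_force_window_scores(self):
        rng = np.random.default_rng(1)
        pwm = pfm_to_pwm(rng.integers(1, 15, (4, 4)).astype(float), pseudocount=0.3)
        pwm.threshold = -1e9  # report every window
        seq = "".join(rng.choice(list("ACGT"), 80))
        hits = scan_sequence(seq, pwm)
        fwd = hits[hits.strand == "+"].set_index("start")["score"]
        for start in range(len(seq) - 3):
            window = seq[start : start + 4]
            expected = sum(pwm.matrix[i, CODE[b]] for i, b in enumerate(window))
            assert fwd[start] == pytest.approx(expected)

    def test_false_hit_rate_matches_p_value(self):
        rng = np.random.default_rng(2)
        pwm = pfm_to_pwm(rng.integers(0, 30, (10, 4)).astype(float), pseudocount=0.5)
        score_threshold(pwm, 1e-3)
        seq = "".join(rng.choice(list("ACGT"), 20000))
        hits = scan_sequence(seq, pwm)
        expected = 2 * (len(seq) - 10 + 1) * 1e-3
        assert len(hits) <= expected + 4 * np.sqrt(expected) + 1


class TestMemeParsing:
    MEME = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF toy1
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
0.90 0.05 0.03 0.02
0.10 0.70 0.10 0.10
0.25 0.25 0.25 0.25
"""

    def test_minimal_meme_round_trip(self, tmp_path):
        path = tmp_path / "toy.meme"
        path.write_text(self.MEME)
        pfms = read_meme_pfms(path)
        assert len(pfms) == 1
        name, counts = pfms[0]
        assert name == "toy1"
        assert counts.shape == (3, 4)
        assert counts[0].argmax() == 0  # A-dominated first column


class TestExtractPromoters:
    @pytest.fixture()
    def toy_genome(self, tmp_path):
        fasta = tmp_path / "g.fa"
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 20000))
        fasta.write_text(f">chr1\n{seq}\n")
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t10001\t12000\t.\t+\t.\tgene_id "gplus";\n'
            'chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tgene_id "gminus";\n'
            'chr1\tsrc\tgene\t101\t300\t.\t+\t.\tgene_id "gedge";\n'
            'chrMISSING\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "gmiss";\n'
        )
        return gtf, fasta, seq

    def test_plus_strand_window(self, toy_genome):
        gtf, fasta, seq = toy_genome
        proms = {p.gene_id: p for p in extract_promoters(gtf, fasta)}
        p = proms["gplus"]
        assert (p.start, p.end) == (7500, 10000)
        assert p.sequence == seq[7500:10000]
        assert not p.truncated

    def test_minus_strand_reads_toward_tss(self, toy_genome):
        gtf, fasta, seq = toy_genome
        p = {x.gene_id: x for x in extract_promoters(gtf, fasta)}["gminus"]
        assert (p.start, p.end) == (6000, 8500)
        assert p.sequence == reverse_complement(seq[6000:8500])

    def test_contig_edge_truncation_and_missing_contig(self, toy_genome):
        gtf, fasta, _ = toy_genome
        proms = {p.gene_id: p for p in extract_promoters(gtf, fasta)}
        assert proms["gedge"].truncated
        assert len(proms["gedge"].sequence) == 100
        assert "gmiss" not in proms


def _occ(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


class TestConsecutiveAsymmetry:
    def test_all_same_strand_exact_binomial(self):
        rows = []
        for i in range(10):
            rows.append(("p%d" % i, 10, 18, "M", 1.0, "+"))
            rows.append(("p%d" % i, 40, 48, "M", 1.0, "+"))
        res = consecutive_homotypic_asymmetry(_occ(rows), max_gap=100)
        assert res.loc[0, "S"] == 1.0
        assert res.loc[0, "p_raw"] == pytest.approx(2 * 0.5**10, rel=1e-6)

    def test_balanced_counts_null(self):
        rows = []
        for i in range(10):
            strand = "+" if i % 2 else "-"
            rows.append(("p%d" % i, 10, 18, "M", 1.0, "+"))
            rows.append(("p%d" % i, 40, 48, "M", 1.0, strand))
        res = consecutive_homotypic_asymmetry(_occ(rows), max_gap=100)
        assert res.loc[0, "S"] == 0.5
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_gap_rule_edge_to_edge(self):
        rows = [
            ("p", 0, 8, "M", 1.0, "+"),
            ("p", 108, 116, "M", 1.0, "+"),  # gap 100 -> excluded at max_gap=100
            ("p", 210, 218, "M", 1.0, "+"),  # gap 94 -> included
        ]
        res = consecutive_homotypic_asymmetry(_occ(rows), max_gap=100)
        assert res.loc[0, "n_same"] == 1

    def test_invariant_under_global_reverse_complement(self):
        # reverse-complementing every sequence flips strands and mirrors
        # coordinates; same-strand pairs stay same-strand, so S is unchanged
        L = 300
        rows = [
            ("p", 10, 18, "M", 1.0, "+"),
            ("p", 50, 58, "M", 1.0, "-"),
            ("p", 90, 98, "M", 1.0, "-"),
            ("q", 10, 18, "M", 1.0, "+"),
            ("q", 60, 68, "M", 1.0, "+"),
        ]
        fwd = consecutive_homotypic_asymmetry(_occ(rows), max_gap=100)
        flipped = [
            (c, L - e, L - s, n, sc, "+" if st == "-" else "-")
            for c, s, e, n, sc, st in rows
        ]
        rev = consecutive_homotypic_asymmetry(_occ(flipped), max_gap=100)
        assert fwd.loc[0, "S"] == rev.loc[0, "S"]

    def test_overlapping_occurrences_merged_to_best(self):
        rows = [
            ("p", 10, 18, "M", 5.0, "+"),
            ("p", 14, 22, "M", 9.0, "-"),  # overlaps; higher score wins
            ("p", 60, 68, "M", 1.0, "-"),
        ]
        res = consecutive_homotypic_asymmetry(_occ(rows), max_gap=100)
        assert res.loc[0, "n_same"] == 1
        assert res.loc[0, "n_opposite"] == 0


class TestPairOrderPreference:
    def test_all_a_proximal_exact_binomial(self):
        rows = []
        for i in range(8):
            rows.append((f"p{i}", 80, 88, "A", 1.0, "+"))  # closer to TSS at 100
            rows.append((f"p{i}", 20, 28, "B", 1.0, "+"))
        tss = {f"p{i}": 100 for i in range(8)}
        res = pair_order_preference(_occ(rows), tss, window=100)
        assert res.loc[0, "n_a_proximal"] == 8
        assert res.loc[0, "p_raw"] == pytest.approx(2 * 0.5**8)

    def test_alternating_orders_null(self):
        rows = []
        for i in range(10):
            a_start, b_start = (80, 20) if i % 2 else (20, 80)
            rows.append((f"p{i}", a_start, a_start + 8, "A", 1.0, "+"))
            rows.append((f"p{i}", b_start, b_start + 8, "B", 1.0, "+"))
        tss = {f"p{i}": 100 for i in range(10)}
        res = pair_order_preference(_occ(rows), tss, window=100)
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_window_excludes_distant_cooccurrences(self):
        rows = [("p", 0, 8, "A", 1.0, "+"), ("p", 500, 508, "B", 1.0, "+")]
        res = pair_order_preference(_occ(rows), {"p": 600}, window=100)
        assert res.empty


class TestDinucleotideShuffle:
    @staticmethod
    def dinucs(s):
        return Counter(zip(s, s[1:]))

    def test_homopolymer_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"

    @settings(deadline=None, max_examples=150)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=60), st.integers(0, 10))
    def test_preserves_dinucleotide_multiset(self, seq, seed):
        shuffled = dinucleotide_shuffle(seq, seed=seed)
        assert self.dinucs(shuffled) == self.dinucs(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]

    def test_matches_brute_force_valid_set(self):
        seq = "ACGCA"
        target = self.dinucs(seq)
        valid = {
            "".join(p)
            for p in itertools.permutations(seq)
            if self.dinucs("".join(p)) == target
        }
        observed = {dinucleotide_shuffle(seq, seed=s) for s in range(200)}
        assert observed <= valid
        assert observed == valid  # small space: all arrangements reachable

    def test_seed_determinism(self):
        seq = "ACGTACGGTCAAGT"
        assert dinucleotide_shuffle(seq, seed=5) == dinucleotide_shuffle(seq, seed=5)

    def test_rejects_length_one(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("A")


class TestCcreEnrichment:
    def _elements(self):
        return pd.DataFrame(
            {
                "chrom": ["p", "p"],
                "start": [0, 100],
                "end": [50, 150],
                "label": ["PLS", "dELS"],
            }
        )

    def test_all_pairs_in_one_class(self):
        occ = _occ([("p", 5, 13, "A", 1.0, "+"), ("p", 25, 33, "B", 1.0, "+")])
        res = ccre_pair_enrichment(occ, self._elements())
        assert res.loc[0, "PLS"] == 1.0
        assert res.loc[0, "dELS"] == 0.0

    def test_far_pairs_not_counted(self):
        occ = _occ([("p", 5, 13, "A", 1.0, "+"), ("p", 300, 308, "B", 1.0, "+")])
        res = ccre_pair_enrichment(occ, self._elements(), pair_window=100)
        assert res.empty

    def test_split_between_classes(self):
        elements = pd.DataFrame(
            {
                "chrom": ["p", "p"],
                "start": [0, 300],
                "end": [50, 350],
                "label": ["PLS", "dELS"],
            }
        )
        occ = _occ(
            [
                ("p", 5, 13, "A", 1.0, "+"),
                ("p", 25, 33, "B", 1.0, "+"),
                ("p", 305, 313, "A", 1.0, "+"),
                ("p", 325, 333, "B", 1.0, "+"),
            ]
        )
        res = ccre_pair_enrichment(occ, elements)
        assert res.loc[0, "n_pairs"] == 2
        assert res.loc[0, "PLS"] == 0.5
        assert res.loc[0, "dELS"] == 0.5

    def test_empty_elements_rejected(self):
        with pytest.raises(ValueError):
            ccre_pair_enrichment(_occ([]), pd.DataFrame(columns=["chrom", "start", "end", "label"]))


class TestPairDistanceHistogram:
    def test_planted_spacing_dominates(self):
        a = [100 * i for i in range(20)]
        b = [100 * i + 12 for i in range(20)]
        hist = pair_distance_histogram(a, b, max_gap=50)
        assert max(hist, key=hist.get) == 12
        assert hist[12] == 20

    def test_empty_inputs(self):
        assert pair_distance_histogram([], [], 100) == {}
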