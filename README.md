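# tfbsgrammar

Analysis toolkit for the *cis*-regulatory grammar of transcription factor
binding sites (TFBS): how the **orientation**, **order**, **copy number**
and **position** of motif kmers in a reporter tile shape transcriptional
activity, measured by massively parallel reporter assays (MPRA), and how
the same grammar shows up as strand asymmetries in promoter sequence.

It is written for regulatory-genomics researchers who design synthetic
TFBS libraries, analyze barcode-level MPRA count tables, or quantify motif
orientation/order biases in genomes. Everything downstream of barcode
counting is covered; raw-read processing is out of scope.

## What it computes

A reporter tile carries motif kmers on a 200 bp neutral background, with
the minimal promoter at the tile's 3' end. Each kmer sits in one of two
orientations: **non-template (NT)** — the kmer as written on the forward
strand — or **template (T)** — its reverse complement. Activity per tile is
the depth-normalized barcode expression

```
expression = log2( (rna / rna_total) / (dna / dna_total) )
```

averaged over barcodes within a replicate and over replicates, after
removing barcodes with DNA count < 3 and tiles with < 3 surviving barcodes.

On top of that the package provides:

* **Library design** — homotypic copy-number sweeps (1–8 copies), all 306
  ordered pairs and 4,896 ordered triplets of an 18-motif roster, each in
  every orientation vector (2^n) at 5 bp / 10 bp / modal-genomic spacing,
  plus single-motif position sweeps in 40 bp bins.
* **Synthetic data** — negative-binomial barcode counts whose expected
  log-ratio follows a planted additive grammar model
  `a = μ_bg + Σ β(m,o)·c^γ + Σ slope·pos + Σ interaction(A,B)`, and
  promoter sequences with planted same-orientation (`p_same`) and
  order-preference (`p_proximal`) biases.
* **Grammar statistics** — orientation t-tests (ratio of linear means =
  strand asymmetry), Levene variance tests, Spearman copy-number and
  position trends, one-way ANOVA across orientation configurations, a
  seeded Monte-Carlo permutation test for copy-number-dependent gains in
  orientation asymmetry, GC/AT-skew associations (Kendall τ) and
  Bonferroni correction throughout.
* **Genome scanning** — PFM → log-odds PWM with an *exact* dynamic-program
  score threshold at a chosen p-value (default 10⁻⁴), two-strand window
  scanning, promoter extraction from GTF+FASTA (−2500 bp to TSS),
  consecutive-homotypic strand asymmetry `S = n_same / (n_same+n_opp)`
  with exact binomial tests, pair order-preference tests, cCRE pair
  enrichment and an Altschul–Erickson dinucleotide-preserving shuffle.
* **Predictive models** — L1-penalized (lasso) regression of tile activity
  on motif counts, strand-agnostic (18 features) vs strand-aware (36
  features), nested 10-fold cross-validation, pooled held-out Pearson r
  and the percent improvement from orientation.

## Worked example

`examples/grammar_statistics.py` simulates a homotypic library for one
motif with a planted orientation preference (β_NT = 0.45, β_T = 0.15 per
copy, saturating dose exponent 0.6) and runs the battery:

```
PPARA 1 copy: NT-T difference +0.355 log2 (linear ratio 1.28), adjusted p 7.07e-13
copy-number trend: Spearman rho +0.361, adjusted p 2.76e-11 (saturating dose planted)
variance difference (Levene): p 0.740 (equal spread planted, so large p expected)
Monte-Carlo gain test (4 vs 1 copies): p 0.0001
```

The linear ratio of 1.28 says tiles with the motif in its preferred
orientation are ~28% more active; the Monte-Carlo p-value says the
orientation gap at four copies is significantly wider than at one copy —
the copy-number amplification of orientation effects.

The other scripts in `examples/` cover library design, count simulation +
quantification (replicate Pearson r ≈ 0.76 under default noise), promoter
strand-asymmetry recovery, and the strand-aware vs strand-agnostic model
comparison.

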