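# Methods

## The model

A reporter tile is a fixed-length neutral background (default 200 bp) with
motif kmers written into defined windows. Orientation is defined relative
to transcription toward the minimal promoter at the tile's right (3') end:
**NT** (non-template) places the kmer on the forward strand, **T** places
its reverse complement there. A placement's position is `offset − L` bp,
in `[−L, 0)`, i.e. distance upstream of the TSS. Coordinates are 0-based
half-open throughout.

The synthetic-data generator's planted activity is additive on the log2
scale:

```
a(tile) = μ_bg
        + Σ_{(m,o)} β(m,o) · c(m,o)^γ(m)          (orientation + dose)
        + Σ_m s(m) · (mean_pos(m) + 100) / 100     (position)
        + Σ_{consecutive (A,B)} δ(A,B)             (order interaction)
```

where `c(m,o)` is the copy number of motif `m` in orientation `o`,
`γ(m) ∈ (0,1]` a saturating dose exponent (power-law chosen because
observed copy-number responses are monotone but bounded), `s(m)` a
position slope per 100 bp toward the TSS, and `δ(A,B)` an order-dependent
pair interaction keyed by which motif comes first. This is exactly the
structure the statistics battery is meant to recover, so parameter-recovery
tests are well-posed.

## Counts

Barcode counts are gamma-Poisson (negative binomial with size parameter
`dispersion`; variance μ + μ²/dispersion). Per tile, the barcode number is
Poisson(50) truncated at 1 and shared across replicates. DNA means are
uniform per barcode (default 100 reads); RNA means scale the DNA mean by
`2^(a + ε)` with tile×replicate noise `ε ~ N(0, noise_sd)`, renormalized
to the RNA depth. Expected per-tile log2(RNA/DNA) is therefore affine in
the planted activity with slope 1 (verified by regression in the tests).

Defaults: `noise_sd = 0.4`, `dispersion = 10`, 100 reads/barcode,
50 barcodes/tile, 3 replicates. These were calibrated once so that the
reference simulation (full 18-motif roster, homotypic copies {1,2,4} plus
position sweeps, two backgrounds with baselines ±0.3) yields replicate
Pearson correlations of roughly 0.75–0.80, the agreement level typical of
reporter libraries of this size. Background 2 is given the lower baseline.

## Quantification

The representation filter is applied twice, as two independently
configurable floors: barcodes with DNA count < 3 are removed (boundary
value retained), then tiles with fewer than 3 surviving barcodes in a
replicate are dropped for that replicate. Barcodes with zero RNA get a
pseudocount of 1 added to both counts; consequently depth invariance
(rescaling a replicate's RNA counts shifts all expressions by a common
constant) holds exactly only for barcodes with positive RNA. Aggregation
is the mean over barcodes, then the mean over replicates present — median
aggregation was considered and rejected to keep the estimator linear in
the planted activity.

## Statistics

* Orientation and order contrasts use Student's two-sample two-sided
  t-test by default (Welch by flag, since variance tests show unequal
  spreads for some motifs). Effect sizes are reported both as the mean
  log2 difference and as the ratio of mean *linear* activities
  (`mean 2^x`), so "x% higher activity" statements are well-defined; the
  two conventions differ and both are emitted.
* Copy-number and position trends are Spearman correlations; the position
  analysis also reports the percent change of mean linear activity in the
  `[−40, 0)` bin relative to `[−200, −160)`.
* The Monte-Carlo gain test uses the statistic
  `|meanNT − meanT|₄ − |meanNT − meanT|₁` with a null built by permuting
  orientation labels independently within each copy-number stratum;
  `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, seeded. Under exchangeability
  the p-value is exactly uniform on its achievable grid, so the type-I
  error at any nominal α on that grid is exact.
* Bonferroni families are per analysis screen (18 motifs, 306 pairs,
  4,896 triplets) and the family size is recorded in every result.
* Strand asymmetry on occurrence sets is
  `S = n_same / (n_same + n_opposite)` over consecutive same-motif pairs
  with edge-to-edge gap below `max_gap`, tested by exact two-sided
  binomial against 0.5. The gap default is 100 bp with 50 bp as a preset
  (both conventions appear in the field); inter-motif distance is
  edge-to-edge, while modal genomic distances are measured start-to-start
  and converted to gaps by subtracting the upstream kmer length.
  Overlapping same-motif occurrences are merged to the higher-scoring one
  before pairing.

## PWM scanning

PFMs (read from minimal-MEME files via Biopython) become log2-odds
matrices with `score = log2(((count + pc·bg)/(colsum + pc))/bg)`. The
score threshold for a target p-value is computed by an exact dynamic
program: scores are quantized to multiples of 10⁻³ and the full score
distribution under the background model is built by position-wise
convolution; the threshold is the smallest *achievable* score whose tail
probability is ≤ p. This matches brute-force enumeration over all 4^w
windows exactly (tested up to width 8). If even the best score is more
probable than p, the threshold caps at the maximum score and is flagged.
Scanning scores every window on both strands (minus-strand hits keep
forward coordinates); windows containing non-ACGT characters are skipped.
Background frequencies default to uniform and should be set to the
scanned genome's composition for genomic work.

The dinucleotide shuffle is the Altschul–Erickson Euler-path construction:
it preserves the dinucleotide multiset exactly (hence mononucleotide
counts and both terminal bases) and, given a seed, is deterministic.

## Promoter simulation

Synthetic promoters are first-order Markov sequences from a dinucleotide
frequency table (uniform by default — real promoter composition, CpG
islands and repeat structure are *not* emulated, so genomic composition
confounds are out of scope for what passing tests demonstrate). Each
promoter is read 5'→3' toward its TSS at the right end and receives one
consecutive homotypic pair whose second member copies the first's strand
with probability `p_same`, and one heterotypic pair whose alphabetically
first member is TSS-proximal with probability `p_proximal` (consistent per
pair across promoters, so a per-pair preference exists). A truth table
(BED6-like) records every planted occurrence; the `score` column flags
homotypic (0) vs heterotypic (1) plantings so the two analyses can be run
on their own ground truth.

## Predictive models

Features are motif counts per tile, either per motif (strand-agnostic) or
per motif×orientation (strand-aware, NT column before T; the two columns
sum to the agnostic count). The penalty is chosen by inner cross-validation
(LassoCV) on each training split of a seeded, shuffled outer 10-fold
split; features are standardized inside each fit and the intercept is
unpenalized. When tiles span both backgrounds the response is centered
within background before fitting — algebraically identical to an
unpenalized background intercept, which sklearn's lasso cannot express
directly. Performance is the Pearson r (and Spearman ρ) of held-out
predictions, per fold and pooled over the concatenated folds; the
improvement metric is `100·(r_aware − r_agnostic)/r_agnostic` on identical
fold assignments. On orientation-symmetric grammars the aware model pays a
small variance cost for its doubled feature count and does not win; it
dominates only when orientation carries signal.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the reference simulation
at ~1,100–6,800 tiles, 20–50 barcodes/tile, 3 replicates, 400 promoters of
600 bp, 10,000-replicate calibration loops and 20-seed model comparisons —
sizes chosen so every planted effect is detectable with comfortable power
while the whole battery stays interactive. Degenerate inputs are handled
explicitly: constant expression flags trends as undefined rather than
erroring; identical constant groups give ANOVA F = 0, p = 1; empty
orientation groups are rejected by name; tile configurations that do not
fit their background are skipped and logged, not fatal; ties in the modal
pair distance break toward the smaller distance, with a documented 10 bp
fallback when no pair lies in the search window.

## Known limitations

* Motif kmers other than the two documented ones (AP1, CREB1) are
  consensus-style synthetic stand-ins; analyses that depend on the exact
  kmer identities of the remaining sixteen factors should load a user
  roster TSV.
* The shipped background sequences are synthetic neutral stand-ins for
  the original genomic backbones (whose coordinates are retained as
  metadata); only their length and neutrality matter to the simulator.
* The count simulator models barcode sampling and tile-level noise but not
  PCR jackpotting, UMI structure, or integration-site effects.
* Genome-scale percentages reported in the literature depend on specific
  database versions (JASPAR, GENCODE, ENCODE cCREs) and are deliberately
  not reproduced; the genomic analyses here validate machinery on planted
  truth instead.
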