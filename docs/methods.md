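# Methods

## Problem and model

A paired methylome experiment compares the per-base modification call sets
of a wild-type bacterium and a methyltransferase-deletion mutant. Loci that
lose their N4-methylcytosine (m4C) calls in the mutant are direct or
indirect targets of the deleted enzyme; genes whose coding sequence and
promoter lose essentially all m4C are prime candidates for
methylation-controlled regulators. `methscreen` operationalises this as a
pure call-set comparison:

* A **call** is identified by the key (contig, 1-based position, strand,
  modification type). Two calls are the same site iff their keys are equal.
* A site is **lost** iff its key occurs in the wild type and not in the
  mutant. Partial methylation (fraction-modified estimates) is deliberately
  not modelled: the only filtering knob is an optional identification-score
  threshold applied to both samples before differencing (calls without a
  score are retained, since they cannot be judged). This makes the
  difference deterministic and order-independent.
* Calls on **either strand** inside a CDS interval count toward the gene.
  m4C motifs are frequently palindromic, producing adjacent opposite-strand
  site pairs; restricting to the coding strand would halve them
  arbitrarily.

Per gene the pipeline reports site-loss fraction (lost / wild-type CDS
sites; defined as 0 when the wild type has no sites, so siteless genes stay
numeric and simply can never pass the screen), abundance loss (lost CDS
sites per CDS base — the "methylation abundance" metric), lost-site
positions relative to the CDS start on the coding strand, and the same
statistics for an upstream promoter window.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `promoter_len` | 300 bp | upstream window scanned for promoter methylation; a common bacterial promoter span, comfortably covering regulatory sites a few bases upstream of the start codon |
| `min_score` | none | optional Phred-like identification-quality floor |
| `bin_size` | 100 ordinals | fixed, non-overlapping ORF-ordinal bins anchored at 0 |
| `density_threshold` | 0.10 | a bin qualifies when **strictly more** than 10% of its *present* genes carry the pathway category |
| `min_site_loss` | 0.80 | candidates must lose **strictly more** than 80% of wild-type CDS sites |
| `min_abundance_loss` | 0.01 | compared after rounding to one decimal percent, so a gene whose abundance loss prints as "1%" (e.g. 0.998%) passes |
| `min_wt_sites` | 1 | no extra floor on wild-type site count beyond having any |
| regulator keywords | regulator, regulatory protein, transcription factor, sigma factor | case-insensitive substring match on the product annotation; configurable because "presumed regulatory gene" definitions vary by annotation pipeline |
| DE rule | \|log2FC\| ≥ 1, padj ≤ 0.05 | applied per time point; when a table carries no adjusted p-values the fold-change bound alone decides (logged) |

Rounding everywhere is **half-up on the percent scale** (via `decimal`,
not banker's rounding): 7/8 → 88%, 11/12 → 92%. This is the convention that
reproduces conventional report tables; `float`-level `round()` would give
87.5 → 88 only by accident of binary representation elsewhere.

## Design choices where the design was open

* **Binning scheme.** Dense regions are called from fixed 100-ordinal bins
  merged when adjacent, not from a sliding window. Published region lists
  in this kind of screen start and end on multiples of 100 with widths of
  one or two bins, which fixed-100 binning with merging reproduces; a
  sliding scan (`step < bin_size`) is available for exploration, with
  overlapping qualifying windows unioned. Region spans are half-open
  `[start, end)`; the label `orf700-orf900` therefore covers ordinals
  700–899.
* **Density denominator.** Density is assigned-genes over genes *present*
  in the bin, not over `bin_size`, so annotations with ordinal gaps are not
  diluted; the two coincide when the annotation is dense.
* **Promoter loss ranks, never filters.** Screens of this kind keep
  candidates with zero promoter loss; promoter loss (like dense-region
  membership) only orders the final table.
* **Coordinates.** GFF3's 1-based inclusive convention is used internally
  end to end; the single conversion to 0-based half-open happens when the
  BED region file is written.
* **Duplicate calls** (same key twice in an input file) keep the
  higher-scoring record — deterministic and input-order-independent.
* **Known metric caveat.** Abundance loss is defined as lost CDS sites /
  CDS length. Published tables of this screen occasionally print figures
  consistent with a slightly different denominator (e.g. 1.3% where
  9/621 = 1.45%); this implementation keeps the footnote definition and
  does not attempt to reproduce such cells.

## Synthetic data: what it emulates, what it does not

The generator builds a complete synthetic study per seed: one contig of
single-interval CDS genes (ordinals 1..n, lengths ~N(900, 300²) bp rounded
to codons, 150 bp intergenic gaps, 8% regulator-like products), a wild-type
methylome at 8 m4C sites/kb over CDS bodies and upstream intergenic
windows, a mutant that loses *all* sites of the planted target genes plus
an independent 30% background fraction of the rest, a pathway table with
30% membership inside planted ordinal spans over a 2% background, and
three-timepoint DE tables where planted genes get ±4 log2FC plus N(0, 0.3)
noise (planted "mixed" genes flip sign at the last time point; null genes
get noise only).

Two placement choices matter for interpretability:

* **Planted targets are densely methylated**: a deterministic
  ⌈15 sites/kb⌉ of CDS (never fewer than 5), matching the density observed
  at archetypal methyltransferase-target regulators (9 sites in a 621 bp
  CDS ≈ 14.5/kb). At the 8/kb background rate a 900 bp gene carries ~7
  sites, which could never show the >1% abundance loss that defines a
  target, so planting at background density would contradict the scenario
  being modelled.
* **Sites are only placed inside CDS bodies and intergenic gaps** (promoter
  placement is clipped to the gap), and the simulated scenario's promoter
  window defaults to the 150 bp gap width. This makes "the mutant loses all
  sites of a planted gene" realizable as an interval deletion that cannot
  collaterally delete a neighbouring gene's CDS sites, so noiseless runs
  recover the planted set *exactly*. For real data the 300 bp default
  stands.

What the generator does **not** emulate: genome sequence and motifs,
kinetic (IPD) signal and per-read evidence, partial methylation fractions,
operon structure, overlapping genes, multi-contig assemblies, or DE count
noise models (fold changes are drawn directly). Passing tests therefore
show that the *arithmetic and set logic* of the pipeline are correct and
that the screen separates planted total loss from 30% background loss; they
do not show robustness to motif-level artefacts or expression-estimation
noise in real data.

Randomness discipline: one master seed, spawned into independent
per-generator streams (`numpy` `SeedSequence`), so each piece regenerates
independently and equal seeds give byte-identical output files.

## Numerical and degenerate-input behaviour

* Fractions with zero denominators (no wild-type sites in CDS or promoter)
  are 0, never NaN.
* Promoter windows are clipped at contig position 1; a gene on a contig
  absent from both methylomes yields an all-zero delta with a warning.
* Ranking is a total order (final tie-break: ascending ordinal), so the
  ranked list is invariant under input permutation.
* A log2 fold change of exactly 0 makes a gene sign-inconsistent (it has no
  direction).
* CDS lengths not divisible by 3 warn but do not error; encoded protein
  length is ⌊L/3⌋ − 1 (codons minus stop).

## Problem sizes used in the test suite

Unit and property tests run on instances of up to 1,000 genes / 60 calls
per gene region (with brute-force oracles for the diff and the region
scan); end-to-end planted-truth tests use 600–800-gene scenarios, and the
recall/precision check aggregates 20 seeded 800-gene scenarios at default
noise. These sizes exercise every code path, including multi-bin merging
and background false positives, while keeping the whole suite fast; the
pipeline itself comfortably handles genome-scale input (a 6,000-gene,
~50,000-call scenario diffs in well under a second).

## Known limitations

* Single-interval CDS genes only; multi-part CDS features are rejected
  (bacterial scope).
* The regulator gate is keyword-based on product text — it inherits
  whatever biases the annotation has.
* The screen is descriptive, not inferential: no statistical test is
  attached to loss fractions or region densities.
* DE tables are consumed as given; no normalisation or DE calling is
  performed.
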