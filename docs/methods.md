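# Methods

## Overview

`tracm7g` implements a five-stage analysis of m⁷G tRNA methylation and its
translational read-out: (1) construction of mature/precursor tRNA
references, (2) TRAC-seq site calling from treated vs untreated small-RNA
libraries, (3) tRNA expression quantification under methyltransferase
knockdown, (4) translation-efficiency (TE) classification from input/RNC
mRNA count tables, and (5) a codon-frequency statistic connecting
m⁷G-tRNA-decoded codons to TE-down genes. A synthetic-data generator
produces every input with planted ground truth, so each stage's recovery
behaviour is measurable.

## Reference construction

Gene records carry the genomic plus-strand sequence, 0-based half-open
intron intervals, strand, anticodon and flanks. Mature references are
built by (i) reverse-complementing minus-strand genes, (ii) deleting
annotated introns, (iii) transcribing to RNA, and (iv) appending the CCA
tail unconditionally — the rule is applied verbatim, so a genomically
encoded CCA is not deduplicated. Precursor references are the unspliced
gene ±100 nt of flank (N-padded with a warning if flank sequence is
short). Identities `len(mature) = len(gene) − introns + 3` and
`len(precursor) = len(gene) + 2·flank` hold for every record. Reads are
mapped to mature references; precursor mapping exists behind the same API
but is not part of the default chain, since cleavage calling is defined on
mature coordinates.

## Read mapping

A deliberately simple deterministic mapper serves the desk scale this
package targets: exact substring search of each read against every
reference (reads and references are compared in RNA space), with an
optional seed-and-extend mode (exact 18-nt 5′ seed, up to `max_mismatches`
in the extension). All equally best placements share the read's weight
1/k, so total assigned weight equals the number of mapped reads; reads
shorter than the seed are unmapped. The mapper's pileups are verified
against an exhaustive brute-force placement oracle in the test suite.
Limitations: no indels, no quality use, mismatches are not tolerated
inside the seed.

## Cleavage statistics and site calling

Per position, `ratio = (starts + c)/(depth + c)` with pseudocount
`c = 0.5` (guards empty numerators; unspecified in the source protocol)
and a depth filter of 20 reads (positions below it are masked in either
library). The default score is `log2(ratio_treat / ratio_untreat)`.
The published formula prints the *quotient of logarithms*
`log2(ratio_treat)/log2(ratio_untreat)`; because both ratios lie in (0, 1],
that expression assigns scores *below* 1 to exactly the sites the assay is
designed to reveal (treated ratio ≫ untreated ratio) and can never exceed
the stated threshold of 3 for them, contradicting the assay's stated
principle. The package therefore defaults to the log-quotient form and
retains the printed form as the selectable `as_printed` mode (with the
untreated ratio clamped to 1 − 10⁻⁹ when it equals 1). Calling uses strict
inequalities — score > 3 and cleavage *rate* > 0.1, the rate being the
treated-library cleavage ratio (the protocol uses "rate" and "ratio"
interchangeably; the treated ratio is the natural reading for a detection
threshold) — and is restricted to reference G positions by default, since
the chemistry is G-specific; the restriction can be disabled to audit
off-G signal. Replicate libraries are pooled before calling.

The consensus motif is the per-position minimal IUPAC code over all call
contexts (5-mers centered on the site, N-padded at reference edges),
admitting bases with frequency ≥ 0.05 by default; with a floor of 0 the
consensus provably matches every contributing context.

## tRNA expression

Abundance uses the chemically untreated libraries only (cleavage distorts
coverage): per-tRNA CPM over total tRNA-mapped weight, and
`log2FC = log2((CPM_kd + 0.5)/(CPM_ctrl + 0.5))`. CPM is a *relative*
measure: knocking down a fraction f of tRNAs by factor φ shifts every
share upward by −log2(1 − f(1 − φ)), so with the default 21 modified among
150 tRNAs at φ = 0.5 the expected measured log2FC of modified tRNAs is
log2(0.5/0.93) ≈ −0.90, not −1. This compositional effect is inherent to
any within-library normalization and is visible in the worked example.

## Translation efficiency

`FPKM = counts·10⁹/(total·length)` with the annotated CDS length and the
column sum as library total (no effective-length correction — no fragment
length model is assumed). `TE = FPKM_RNC/FPKM_input`; genes with input
FPKM < 1 in either condition, or with undefined TE, are "filtered".
Classes use the log2 TE change (knockdown/control) with an inclusive ±1
cutoff. Both cutoffs are configuration keys, since the source analysis
states no numeric values. Note a structural consequence of
per-million normalization: suppressing the RNC signal of one gene group
inflates all other genes' RNC FPKM, so true effects are measured slightly
compressed (see "Generator" below).

## Codon statistic

Anticodons map to decoded codons by strict reverse complement (default);
`wobble34` additionally admits G34:U and U34:G third-position pairings
(inosine excluded). Per-gene frequency is the fraction of codons of a CDS
(start codon included, terminal stop excluded) belonging to the pooled
m⁷G codon set. Frequencies are compared across TE classes at the gene
level: one-way ANOVA omnibus (scipy) plus contrasts of each class against
the TE-down reference. The default family-wise adjustment is a seeded
label-permutation max-|t| null (exact finite-sample validity, no
distributional assumptions; raw p-values use each contrast's own
permutation distribution so adjusted ≥ raw by construction); classical
Dunnett (scipy) is available for large balanced designs and is used as a
cross-check in the tests.

## IHC H-score

H = Σᵢ i · bin(pᵢ) over intensity levels i ∈ {0..3}, where bin maps the
percent of cells to 0–4 via left-closed intervals [0,5), [5,25), [25,50),
[50,75], (75,100] — 75 % exactly stays in bin 3, matching the stated "50
to 75" wording. Scores ≥ 6 classify as high expression. The score is
monotone under upward mass shifts only when the donor's bin is unchanged;
the binning itself is sub-additive, which the tests document.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
tRNA biology in detail:

* **tRNA set** — `n_trnas = 150` random sequences of mature length 70–90
  nt, 25 % intron-containing, both strands, gtRNAdb-style names carrying
  the anticodon. `n_modified = 21` tRNAs (the study's reported count of
  m⁷G tRNAs, kept a minority of a realistically larger species pool so
  CPM composition bias stays modest) carry a G at mature position 46
  (0-based 45, the canonical m⁷G46 position) with a ±2 context drawn from
  DURGY (central R realized as G). Modified tRNAs receive distinct
  anticodons so the decoded codon set is well defined.
* **Libraries** — four libraries (treated/untreated × knockdown/control),
  one replicate by default (configurable), 50 000 reads each. Cleavage at
  site i yields a fragment whose first base is i; a treated-library read
  from a modified tRNA starts at the site with probability
  `cleavage_prob_site = 0.6`; otherwise background starts occur with
  per-position probability 0.005, and the remainder are intact 5′ ends.
  Reads run to the 3′ end, capped at 75 nt; qualities are constant
  ('I') — the pipeline ignores them and trimming is out of scope.
  Knockdown multiplies modified tRNAs' sampling weights by
  `knockdown_fc = 0.5`.
* **Transcriptome** — `n_genes = 2000` CDSs of 100–400 internal codons
  (ATG start, single terminal stop, no internal stops). A fraction
  `enriched_fraction = 0.1` of genes draws each codon from the m⁷G set
  with probability background + `codon_margin = 0.1`; exactly these genes
  are the true TE-down set. A further 5 % are true TE-up; the rest null.
* **Counts** — negative binomial around expected counts; log-normal
  expression (σ = 1) and baseline TE (σ = 0.25); expected counts per
  library sum to `depth_per_library = 2·10⁶`. Input expression is
  identical between conditions; the expected RNC share of down/up genes
  is scaled by `te_effect_fc = 0.5` (resp. its inverse) under knockdown
  only. Dispersion defaults to 0.01 — technical/shot-noise scale. With a
  biological-scale dispersion (0.1) and single libraries, a ±1 log2
  threshold has no discriminating power at all (SD of the TE change
  estimate ≈ 0.9), so a small default is the only choice consistent with
  a usable null false-positive rate; users fitting real replicated data
  should estimate dispersion from it instead.

What the generator does *not* model: tRNA secondary structure and
modification-induced RT stops other than the planted cleavage, sequencing
errors, adapter content, paired ends, isoform structure, length biases,
and correlated expression. Passing recovery tests therefore demonstrates
the correctness and calibration of the statistics under their own
assumptions, not performance on real libraries.

## Known behaviour at the classification boundary

With the generator's `te_effect_fc = 0.5`, the true TE log2 change of
affected genes is −1 — exactly the inclusive classification threshold.
Any unbiased noise then places about half of the truly-down genes on
either side, so TE-down recall concentrates near 0.5 (and FPKM
renormalization compresses the measured effect slightly further). The
acceptance suite measures and reports this honestly; recall near ½ at the
boundary is the expected behaviour, not an implementation defect. False
TE-down calls among null genes remain rare (≲ 0.1 % at default depth).

## Numerical and design choices

* 0-based half-open coordinates internally; BED12 blocks encode exons.
* Pseudocounts: 0.5 on cleavage starts/depth and 0.5 CPM in expression.
* Ties in mapping split fractionally; calling pools replicates.
* Permutation p-values use the (1 + exceedances)/(1 + B) estimator.
* Degenerate comparisons (all observations identical) return F = 0, p = 1.
* All randomness flows through numpy Generators seeded from a single
  config seed (per-stage independent streams), so every output is
  reproducible byte-for-byte.

## Problem sizes

The test and acceptance runs use deliberately small instances chosen as a
desk-scale working point: site-recovery runs use 20 tRNAs × 5 000 reads ×
10 seeds; expression runs the full 150-tRNA default; TE recovery runs
2 000 genes at 2·10⁶ fragments; codon-statistic power uses 50 replicates
of 300 genes at 3·10⁵ fragments with 2 000 permutations, and calibration
200 label shuffles with 1 000 permutations.
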