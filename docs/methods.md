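# Methods

This document specifies the models, algorithms and numerical conventions
implemented by `sweetbsa`. Every quantitative claim here is either a
definition or something computed by the test suite / acceptance script; no
empirical results beyond those are asserted.

## 1. Study design being emulated

A biparental cross between a fast- and a slow-sugar-degrading sweet-corn
inbred is advanced to F6 by single-seed descent (F1 + 5 selfing
generations). The mapping trait is the soluble-sugar reduction over 0–72 h
of postharvest storage (mg per g fresh weight); it may be negative for lines
that gain sugar (e.g. by starch remobilisation), so transgressive
segregation in both directions is expected and simulated. The most extreme
`n_bulk` lines at each tail form a high and a low bulk; parents are
sequenced at ~10×, bulks at ~30×.

## 2. Simulator

### 2.1 Genotypes

Each line starts as an F1 (one haplotype per parent) and is selfed
`n_selfing_generations` (default 5) times. Each meiosis applies a Markov
recombination process along the locus list: between adjacent loci at map
distance *d* Morgans the gamete switches parental phase with the Haldane
probability r = (1 − e^(−2d))/2; the first locus of each chromosome draws
its phase uniformly. Residual heterozygosity per locus is (1/2)^5 = 3.125%
in expectation, which the test suite verifies.

**Map density.** The default is `cm_per_mb = 3.0`. The simulated genome is
scaled to 10 chromosomes × 60 Mb (600 Mb, roughly a quarter of a maize
genome) to keep desk-scale runtimes; a maize-like genetic map of ~150–200 cM
per chromosome is conserved under that physical scaling by raising the
recombination density, giving 180 cM per 60 Mb chromosome (~18 Morgans
genome-wide). Using a typical physical-scale value (1 cM/Mb) on shortened
chromosomes would quarter the genetic map, producing unrealistically long
linkage blocks: QTL peaks then wander megabases from the causal locus and
null drift excursions widen correspondingly.

### 2.2 Phenotypes and bulks

Phenotype = `baseline` + Σ QTL effect × dosage + N(0, `phenotype_noise_sd`²),
where dosage of the trait-raising allele is 0/0.5/1 and each configured QTL
is snapped to the nearest simulated locus. Defaults: noise SD 6 mg/g and a
single 28 mg/g QTL (the parental contrast), so one QTL of ~4.7× the noise SD
reproduces a wide, transgressive population range. Absolute sugar contents
are derived per line: content at 0 h ~ N(84.47, 5²) mg/g, content at 72 h =
content₀ − reduction, content at 8 h assumes 60% of the reduction is
realised early. Bulks are the `n_bulk` (default 30) largest/smallest
reductions; ties break by line index (stable sort).

### 2.3 Variants and reads

Two variant classes are emitted, mirroring real resequencing call sets:

* **Segregating loci** (`n_snps` = 650/chromosome): the parents carry
  different alleles (P1 = REF, P2 = ALT). Only these are informative for the
  scans; the strict parental-polymorphism filter retains them. At 600 Mb
  this gives ~9.5 scan loci/Mb, so a 1 Mb smoothing window averages ~10
  loci.
* **Background variants** (`n_background` = 7500/chromosome, ~125/Mb): both
  parents share the same non-reference allele, i.e. variants against the
  reference genome that are monomorphic in the cross. They fail the
  polymorphism filter exactly as in real data but still carry
  functional-impact annotations, so they are what the effective-variant
  interval filter actually sees. Without this density split the scan-locus
  density alone (~9.5/Mb × ~1.2% HIGH+MODERATE) would leave most true
  intervals without an effective variant.

Impact labels are drawn independently per variant with probabilities
(HIGH, MODERATE, LOW, MODIFIER) = (0.002, 0.01, 0.05, 0.938), approximating
genome-wide SnpEff proportions; a configurable fraction (default 10%) of
variants is labelled InDel for filter bookkeeping. Read depths are Poisson
(`parent_depth_mean` 10, `bulk_depth_mean` 30); ALT read counts are Binomial
in the error-adjusted allele frequency (per-read flip probability
`seq_error_rate` = 0.001). The true bulk ALT frequency at a segregating
locus is the mean allele dosage of the bulk's members.

All randomness flows from `SimConfig.seed` through one
`numpy.random.Generator`, so all outputs (including VCF/GFF3 text) are
byte-identical across runs.

### 2.4 What the simulator does *not* model

Read-level artifacts (FASTQ, alignment, indel realignment), epistasis, G×E,
segregation distortion, linked QTL interference, and annotation realism
(impacts are independent of gene positions; the GFF3 is a uniform tiling of
3 kb genes every 40 kb, ~25 genes/Mb).

## 3. Statistics

For a biallelic locus with bulk ALT frequencies f_H, f_L:

* **ED** = √((f_H−f_L)² + ((1−f_H)−(1−f_L))²) = √2·|f_H−f_L|, raised to the
  fourth power (**ED⁴**) to suppress background noise before smoothing.
  Range 0…√2 (ED) and 0…4 (ED⁴).
* **G** = 2·Σᵢ nᵢ ln(nᵢ/êᵢ) over the 2×2 table of (ref, alt) × (high, low)
  read counts, with expected counts êᵢ from the table margins under
  independence and the convention 0·ln 0 = 0 (implemented with
  `scipy.special.xlogy`; cross-checked in the tests against
  `scipy.stats.chi2_contingency(..., lambda_="log-likelihood")`). G is NaN
  only for an all-zero table; such loci are dropped and logged.

Both statistics are invariant under bulk swap and allele relabelling
(property-tested).

### 3.1 Smoothing

* **ED⁴**: unweighted mean over windows of `window_bp` (1 Mb) anchored every
  `step_bp` (50 kb) from position 0; empty windows emit no value. Each locus
  takes the value of the containing window whose centre is nearest the locus
  (anchor index round((pos − window/2)/step), clipped to the containing
  range).
* **G′**: tricube-kernel local average — loci within window/2 on either side
  contribute with weight (1 − (d/(window/2))³)³, normalised to sum to 1. An
  isolated locus keeps its raw G.

Smoothing never crosses chromosome boundaries.

### 3.2 Threshold

The association threshold is the genome-wide empirical `threshold_quantile`
(default 0.995) of the smoothed per-locus track, computed with NumPy's
linear-interpolation quantile; loci strictly above it are flagged. By
construction ~0.5% of loci are flagged in every scan, null or not — the
threshold controls the *fraction*, not the false-positive rate.

## 4. Region calling

1. **Runs**: per chromosome, consecutive flagged loci are merged while
   separated by ≤ `merge_gap_bp` (1 Mb); a region spans [first, last]
   flagged locus (1-based, closed).
2. **≥10-loci rule**: regions with fewer than `min_loci_ed` (10) supporting
   loci are discarded on the ED side (`min_loci_gprime` defaults to 1 — the
   guard is an ED-side convention; both are configurable).
3. **Effective-variant filter**: a retained region must contain ≥1 variant
   with HIGH or MODERATE impact in the *unfiltered* table (closed interval).
4. **Consensus**: every overlapping ED×G′ pair contributes the intersection
   interval. Consensus regions inherit effective-variant support from both
   parent sets by construction; their `n_effective` is recomputed and
   reported but not re-filtered.
5. **Genes**: a gene counts if its interval overlaps the region by ≥1 bp
   (closed-interval overlap).

`span_mb` = (end − start)/10⁶ rounded to 2 dp with Python's round-half-even.
Note one bookkeeping subtlety this exposes: an interval of 1,085,068 bp has
span 1.0851 Mb and therefore prints 1.09, even though reports elsewhere
sometimes show such values truncated to 1.08; the package keeps the
round-half-even convention uniformly rather than matching any particular
printed rounding.

## 5. Candidate-gene screens

Genes in consensus regions are screened by (a) expression — FPKM strictly
above `expression_cutoff` (1.0) in any screened tissue (default seed,
endosperm); genes absent from the matrix fail; (b) a case-insensitive
keyword match of the functional-annotation text against sugar-metabolism
terms (sugar, sucrose, carbohydrate, kinase, glycosyl, amylase, invertase,
fggy). Ranking is a stable descending sort by keyword flag, then expression
flag, then the descriptive |low − high| contrast of mean 2^−ΔCT qPCR
expression; no hypothesis test is performed. When no real expression or
annotation tables are configured, the report stage substitutes clearly
labelled synthetic stand-ins so the pipeline stays runnable end to end.

## 6. Numerical conventions

* Quantiles: NumPy `method="linear"`; "above threshold" is strict (>), so
  with n loci about ⌊0.005·(n−1)⌋ are flagged (the realised fraction
  oscillates around 0.5%).
* Rounding: all 2-dp reports use Python `round` (round-half-even).
* Coordinates: 1-based inclusive throughout (VCF/GFF3 convention).
* Tie handling: bulk selection and candidate ranking use stable sorts.
* Seeds: derived panel seeds in `scripts/acceptance.py` are drawn in
  [0, 2³¹) from `numpy.random.default_rng(--seed)`.

## 7. Limitations

**Phantom null peaks.** The 99.5% empirical threshold flags the top 0.5% of
smoothed loci in every dataset. Under the null these flagged loci are not
scattered: a 30-line bulk's allele-frequency sampling drift (SD ≈ 0.13 per
bulk per locus) is correlated along chromosomes by linkage, so flagged loci
concentrate into one or two genome-wide excursions of roughly 1–4 Mb. At the
marker density needed for megabase-scale mapping resolution (~10 loci/Mb),
such an excursion typically contains ≥10 flagged loci, is detected by *both*
ED⁴ and G′ (they are computed from the same reads, so their noise is
strongly dependent — the two-method consensus is not an independent
replication), and contains effective variants at any background density that
lets true multi-Mb intervals pass. Consequently the pipeline emits an
occasional spurious consensus region under the null, and the acceptance test
demanding zero consensus regions in ≥9/10 null seeds fails by design rather
than be weakened; the quantile threshold controls a fraction, not an error
rate. Remedies outside the present method definition include
permutation-based thresholds, simulation-calibrated null bands (as in
G′-based pipelines with theoretical null distributions), or requiring
replication across independent bulk pairs.

**Scale.** The 600 Mb genome, locus counts and depths are a desk-scale
stand-in; absolute region counts and coordinates of any real study are not
reproduced, only the method's behaviour (funnel shape, recovery, spans).
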