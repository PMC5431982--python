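# Methods

## Allelic-imbalance model

Each somatic mutation contributes two binomial observations: k_D mutant reads
of n_D at the DNA level (WES) and k_R of n_R at the RNA level (RNA-seq).
The test compares

* **H1** (imbalance): k_D ~ Bin(n_D, p_D), k_R ~ Bin(n_R, p_R) with
  independent p_D, p_R ~ Beta(α, β);
* **H0** (balance): both counts share one p ~ Beta(α, β).

Both marginal likelihoods are conjugate beta-binomial integrals, so the Bayes
factor reduces to a ratio of Beta functions (binomial coefficients cancel):

    log BF₁₀ = logB(α+k_D, β+n_D−k_D) + logB(α+k_R, β+n_R−k_R)
             − logB(α, β) − logB(α+k_D+k_R, β+n_D+n_R−k_D−k_R)

evaluated with `scipy.special.betaln` and reported as log₁₀ BF. The model is
symmetric in (DNA, RNA) and depends on the data only through the four counts.

**Assumptions.** Reads are independent draws from the allele pool at the
locus (no mapping bias, no duplicate structure); DNA and RNA libraries are
independent given the true fractions; the Beta prior is exchangeable across
loci. The test is intentionally two-sample and unpaired at the read level —
pairing is at the mutation level (same specimen), which is what makes the
comparison robust to tumor purity and global copy number.

**Decision rule.** A mutation is significant when BF > 10 strictly (the
conventional "strong evidence" threshold); the sign of
AFD = RNA-VAF − DNA-VAF labels it sig-pos-AFD or sig-neg-AFD. AFD = 0 is
never significant, and BF exactly at the threshold is not significant.
Defaults α = β = 1 (uniform); both are configurable (`BFModelParams`) for
alternative calibrations, but no value other than (1, 1) is used anywhere in
the shipped analyses. No multiple-testing correction is applied to the BF —
it is a per-mutation evidence measure, and the calibration check below keeps
the null call rate under 1% at typical depths.

## Preprocessing funnel

| stage | rule | convention |
|---|---|---|
| depth | keep if DNA depth ≥ 10 **and** RNA depth ≥ 10 | boundaries inclusive ("no less than") |
| hypermutation | drop samples with mutations/Mb > 10 | strict `>`; denominator `exome_size_mb` defaults to 38 (a standard exome target size; the rate's denominator is otherwise unspecified, so it is configurable) |
| multi-mutant genes | drop all records of a gene with ≥ 2 records *in the same sample* | per-sample scope: a gene mutated once in each of two samples is kept in both |
| copy-neutral | keep if the position falls in a same-sample segment with −0.15 < log₂ ratio < 0.15 | strict on both sides; loci covered by **no** segment are treated as non-neutral and removed |

The copy-neutral restriction is applied only to the missense analysis, not
globally — decay and retention effects are defined relative to the same-locus
DNA fraction and do not require copy neutrality. Every filter returns a
`FilterReport` (in = out + removed) so the funnel is auditable.

## PTC geometry and NMD classification

All distances are measured in **spliced (mRNA) coordinates**: the
exon-junction-complex model concerns the mature transcript, not the genome.
Conventions:

* For a nonsense SNV the PTC is the codon containing the mutated base; the
  **codon start** (1-based CDS nt) anchors all distances. For frameshifts the
  PTC position must be supplied (`ptc_cds_pos`, mirroring upstream
  annotation); a naive re-translation fallback (shift the frame at the indel,
  translate to the first stop) is available when the model carries a CDS
  sequence (`allow_retranslation`).
* `dist_last_junction` = (transcript coordinate of the last base of the
  penultimate exon) − (PTC transcript coordinate). Zero means the PTC sits on
  the final base before the last junction; negative means the PTC is
  downstream, i.e. in the last exon.
* NMD-sensitive ⇔ not in the last exon **and** `dist_last_junction ≥ 50`.
  The boundary at exactly 50 nt is classified sensitive by default; published
  statements of the rule disagree on the boundary, so it is configurable
  (`nmd_boundary_inclusive`). The region label
  {last_exon, penultimate_ge50, penultimate_lt50, other} partitions all PTCs,
  and the NMD class is a deterministic function of (region,
  `dist_last_junction`).
* Single-exon transcripts have no junction; the PTC is in the (only = last)
  exon and therefore insensitive.
* Splice-site classification covers only the canonical ±2 intronic
  dinucleotides, strand-aware: donor offsets +1/+2 (G/T of the GT
  dinucleotide) after an exon end, acceptor −2/−1 (A/G of AG) before an exon
  start. Deeper intronic positions are rejected.
* One transcript per gene; when a GTF carries several, the longest CDS wins
  (isoform choice can flip the 50-nt classification, so the selection is
  logged).

## Downstream statistics

* **Paired VAF test**: one-tailed paired t on (RNA-VAF, DNA-VAF) pairs via
  `scipy.stats.ttest_rel`; degenerate inputs (n < 2, zero-variance
  differences) raise rather than returning NaN.
* **Exact 2×2 test**: in-package log-space hypergeometric enumeration with
  the R/scipy two-sided convention (sum all tables with point probability ≤
  (1 + 1e-7) × observed); `greater` tests enrichment of cell *a*. A batch API
  groups tables by margins so exhaustive grids evaluate in seconds. Checked
  against `scipy.stats.fisher_exact` and an independent scipy-hypergeometric
  enumeration in the tests.
* **Gene AI enrichment**: per gene, one-sided Fisher on (gene focal, gene
  other) vs (background focal, background other), where the background is all
  other genes in the same result set (the natural within-cohort contrast; a
  per-tumor-type run simply passes that subset). A Benjamini–Hochberg column
  is emitted alongside the raw p-values but is not used for filtering — the
  display threshold is −log₁₀ p > 2.5, and the ranked-list export (.rnk,
  descending −log₁₀ p, ties broken alphabetically for determinism) feeds
  preranked GSEA externally.
* **Spectra / Ts:Tv**: the 12 substitutions collapse onto six
  strand-symmetric classes (no trinucleotide context); transitions are A↔G,
  C↔T. Class × group tables are compared with Pearson chi-square
  (`scipy.stats.chi2_contingency`, no continuity correction).
* **Cumulative ratio curves**: bin k counts all mutations with covariate
  value in [0, k·width) (left-closed, right-open), ratio = events/total,
  empty bins reported with total 0 and a NaN ratio.

## Synthetic cohorts

The generator emulates the structure of a tumor WES+RNA-seq mutation cohort
with known ground truth; it is the test bed for every stage.

* **Transcripts**: per gene, 2–12 exons of 60–400 nt with 200–2,000 nt
  introns, random strand, CDS covering 60–90% of the spliced length.
* **Category mixture**: per-tumor-type presets (BRCA default, plus HNSC,
  KIRC, LUAD, STAD) matching the published cohort proportions, renormalized
  to sum to one.
* **Allele fractions**: true DNA fraction p ~ Beta(8, 12) (mean 0.4, the
  typical bulk-tumor somatic VAF scale); `fixed_dna_fraction` pins p to a
  point when an experiment calls for a single effect size.
* **Effects**: NMD is a per-transcript survival factor r — mutant transcripts
  survive decay at rate r, so the observable mutant RNA fraction is
  `r·p / (r·p + (1 − p))` (default r = 0.25, a strong but incomplete decay).
  Whether a truncating mutation is truly NMD-sensitive is derived from the
  simulated transcript's geometry by an independent brute-force walk over the
  concatenated exons, so the annotation code can be validated against the
  simulator's truth. Splice-site mutations get the same mapping with a factor
  > 1 (default 4, intron retention favoring the mutant allele). Everything
  else is unaffected (RNA fraction = DNA fraction).
* **Depths**: negative-binomial around the configured means (default 80×/80×,
  dispersion 8) to emulate uneven capture and expression-dependent RNA
  coverage; `depth_dispersion = None` gives exact depths for fixed-depth
  experiments. Counts are binomial draws at the true fractions.
* **Copy number**: chromosomes tiled with segments, 80% neutral (log ratio
  within ±0.12), the rest at ±0.2–0.8.
* **Outliers**: 2% of samples are hypermutated (15× the mean burden of 60
  mutations/sample, putting them above 10/Mb on a 38 Mb exome).
* One seeded generator drives every draw in a fixed order: outputs are
  reproducible bit-for-bit per seed.

**What the generator does not model** — and therefore what passing tests do
not establish about real data: mapping and reference bias, PCR duplicates,
tumor purity and subclonal structure, expression-level differences between
genes beyond depth dispersion, multiple isoforms per gene, exon skipping as
an alternative to intron retention, positional mutation hotspots, and any
correlation between mutation category and gene identity. Recovery rates
measured here are upper bounds for real cohorts.

## Problem sizes and numerical choices

The shipped checks use: the full Bayes-factor grid with totals ≤ 30 against
64-node Gauss–Legendre quadrature (exact for these polynomial integrands;
tolerance 1e-6, observed agreement ~1e-14); all 2×2 tables with total ≤ 60
against exhaustive enumeration (tolerance 1e-12); 10,000 null mutations at
depth 50 for calibration (false-call rate ≤ 5%, observed ~0.5%); a ~30,000-
mutation truncating-rich cohort at the power conditions (DNA fraction 0.4,
exact 80×/80× depths, retention 0.25) for NMD recovery, sized so the
Monte-Carlo error (~0.3%) is small against the ≥ 80% recall bound (the
enumerated exact power of the BF rule at those conditions is 80.9%); 1,000
random transcripts for the geometry oracle; and a ~10,000-mutation cohort for
the depth-cutoff grid. Floats in result tables are written with 6 significant
digits; determinism is asserted at the byte level with manifest timestamps
excluded.

## Known limitations

* The Bayes-factor model ignores overdispersion within a library
  (beta-binomial read noise); at very high depths this makes the test
  anti-conservative for small real fluctuations.
* Frameshift PTC positions are taken from the input (or a naive
  re-translation); no splice-aware re-annotation is attempted.
* One isoform per gene; genes whose dominant isoform differs between samples
  will be misclassified by the 50-nt rule in either direction.
* The enrichment background is the whole result set passed in; cohort
  composition effects (e.g. mixing tumor types) are the caller's
  responsibility.
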