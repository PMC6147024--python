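# Methods

## Units and coordinate conventions

All internal coordinates are 0-based, half-open. The only format that
converts is the Bismark coverage dialect (1-based, inclusive), handled by
the reader/writer pair in `rrbs.py`. MspI recognises `CCGG` and cuts
between the first C and the `CGG`, so every cut position is match start
+ 1; both chromosome termini close fragments, and before size selection
the fragments of a chromosome tile it exactly. `N`-containing sites never
match. The default size-selection window is 40–220 bp, a typical RRBS
library window; it is configurable because protocols differ.

## Fragment quantification

Per-CpG methylated/unmethylated counts are pooled over the CpGs of a
fragment: m = Σ n_meth / Σ (n_meth + n_unmeth). This read-weighted pooling
(rather than a mean of per-CpG proportions) keeps the estimate aligned
with its count evidence: a CpG observed 30× moves the fragment estimate
more than one observed 3×. Coverage standardisation has two knobs: a cell
(fragment × sample) is covered at ≥ `min_reads` total reads (default 10),
and a fragment enters the analysis only when covered in
≥ `min_samples_per_group` samples in each group (default 3 of 6). Both
defaults are package choices recorded in the run manifest; they are the
kind of threshold that varies between RRBS studies and should be set to
the protocol at hand.

## Differential methylation

The DMF test is a one-way ANOVA (two groups) on per-sample fragment
proportions — for two groups F = t², so the statistic is elementary and
easily cross-checked. p values feed Benjamini–Hochberg across all tested
fragments; fragments failing the coverage quorum are excluded *before*
adjustment (they change m) and counted. The DMF rule is a conjunction:
q ≤ α (default 0.05) **and** |mean difference| ≥ δ (default 0.25), so a
precisely measured 5% shift is never called. The sign convention is
diff = mean(constitutive) − mean(inducible); hypomethylation in the
constitutive-like group appears as negative differences and
`direction = "hypo"`.

Two documented alternatives ship behind flags because the field is split
on both: a coverage-weighted ANOVA (read-depth weights, normalised so the
degrees of freedom match the unweighted test; it reduces exactly to the
plain ANOVA under equal weights), and a paired signed-rank variant of the
global group comparison (fragments as pairs) next to the default unpaired
rank-sum test on fragment-wise group means. Proportions are tested
untransformed; at the depths targeted here (tens of reads per CpG,
fragment pools in the hundreds) the proportion noise is approximately
symmetric and the null calibration is verified by simulation (raw
p ≤ 0.05 rate 0.05 ± 0.02 at 6 vs 6, φ = 0.05, depth 30), slightly
conservative if anything.

Degenerate inputs: a fragment with zero variance within and between groups
gets p = 1 by convention (no evidence either way) and is logged; rank-test
p values are floored at the smallest positive double to avoid reporting
an exact zero from normal-approximation underflow.

`probe_group_compare` applies the identical ANOVA + BH machinery to an
externally supplied probe × sample beta matrix, which covers array-style
(450K-like) two-group comparisons without any array-specific code.

## Differential expression

The test is Welch's t on log2(FPKM + 1) — log-normal expression noise
makes the t test on logs exact in the generator's world, and Welch is the
robust default at n = 6 per group. The fold-change gate uses group means
of raw FPKM with a pseudocount: lfc = log2((mean_B + ε)/(mean_A + ε)),
ε = 1 by default. The DEG rule follows the printed thresholds exactly:
q < 0.05 strict, |lfc| ≥ 2 inclusive. Genes that are all-zero across
samples are excluded and counted; constant genes get p = 1. FPKM is
accepted as given — normalisation belongs upstream.

Matrix scaling for heatmap export: `mean_centered_log2` subtracts the row
mean of log2(FPKM + ε); `zscore` additionally divides by the row sample
standard deviation (ddof = 1), with zero-variance rows emitted as zeros
and flagged rather than NaN.

The over-representation statistic is the upper-tail hypergeometric
P(X ≥ k) with BH across a user-supplied collection of sets (GMT reader
included); gene-set content is deliberately out of scope.

## Integration

Promoter = TSS − 5 kb to TSS + 1 kb in transcription orientation,
reflected for minus-strand genes and clipped to the chromosome. Gene
body = transcript span minus the promoter window. For element
classification a fragment takes the first class with ≥ 1 bp overlap under
the precedence promoter > exon > intron, else intergenic; promoter windows
are carved out of exons/introns so a TSS-proximal exonic base counts as
promoter (no double counting). Repeat families annotate a fragment when
they cover ≥ 50% of its length, independently of the element class. Both
rules are package choices — assignment conventions differ between
pipelines — and are configurable and recorded in the manifest.

DMF–DEG attribution is per gene: a DMF overlapping gene X's promoter and
gene Y's body is reported for both, each in its own context. Enhancer
attribution requires user-supplied gene-linked intervals (BED with the
gene id in column 4); no default enhancer map is bundled because
enhancer–gene assignment is assembly- and resource-specific.

Spearman correlations use average ranks for ties. The p value uses the
t approximation for n ≥ 10 and exact permutation enumeration (two-sided on
|rho|) below that; at the design size n = 12 the t approximation applies,
while the exact path serves small constructed fixtures. The per-sample
global methylation statistic used for all correlations is the median
fragment methylation, matching the descriptive global summary. The default
regulator panel is the DNA-methylation machinery (DNMT1, DNMT3A, DNMT3B,
UHRF1, UHRF2, TET1–3, APOBEC3F/G); the bundled 30-gene viral-mimicry panel
contains the nine canonical type-I-interferon / dsRNA-sensing genes most
prominently tied to hypomethylation-induced viral mimicry (IFI44, IFI27,
OASL, IL29, IFNB1, IRF7, DDX58, IRF1, TLR3) completed with standard
interferon-stimulated genes (IFIT/IFITM/ISG/MX/OAS families, IRF9,
STAT1/2, CXCL10, DDX60, IFIH1, IL15); both are plain-text data files the
user can replace.

The flow-cytometry helper computes
log2((MFI_antibody,treated − MFI_isotype,treated) /
(MFI_antibody,mock − MFI_isotype,mock)) and refuses non-positive
background-subtracted differences as unusable measurements.

## The synthetic-data generator

The generator emulates a 6-vs-6 cell-line panel in which group B
(constitutive-like) is globally hypomethylated relative to group A
(inducible-like), preferentially outside promoters and exons. What it
models, per stage:

- **Genome** (`make_genome`): per chromosome (default 2 × 500 kb), a
  CpG-depleted random background with MspI sites planted every ~200 bp,
  CpG-island promoters (dense `CCGG`/`CG` around each TSS — the reason
  RRBS enriches for promoters), non-overlapping multi-exon gene models
  with ≥ 10 kb intergenic gaps, and repeat intervals per family
  (L1/L2/Alu/MIR/ERV subfamilies/satellite) at configurable genome
  fractions with family-typical lengths.
- **Methylome** (`make_methylome`): each fragment takes one class — its
  majority repeat family if any, else its element class — and a true
  group-A proportion of baseline[class] + fragment noise (sd 0.04),
  group B adds the class delta; everything clips to [0.01, 0.99].
  Per-sample proportions add a per-sample global offset (sd 0.02), which
  is what gives samples distinguishable global methylation ranks for the
  correlation analyses. Default baselines/deltas: promoters low (0.10)
  and unchanged, exons unchanged, introns −0.12, intergenic 0.66 → −0.19,
  repeat families −0.10 to −0.19 with the largest losses in L1 and ERV1.
  With the default genome composition the planted global medians land
  near 0.63 (A) and 0.47 (B).
- **Counts** (`sample_counts`): per fragment × sample, a gamma depth
  multiplier (mean 30 reads/CpG, shape 5) with per-CpG Poisson depths — a
  negative-binomial marginal — and beta-binomial methylated counts with
  overdispersion φ = 0.05 around the per-sample true proportion.
  Beta-binomial over-dispersion and gamma-Poisson depth are the standard
  noise assumptions for bisulfite count data; the generator's φ → 0,
  depth → ∞ limit recovers the truth to ±0.02, which the tests assert.
- **Expression** (`make_expression`): log-normal FPKMs (baseline
  log2 ~ N(3, 1.5), residual sd 0.5). Planted DEGs (default 150 of 3000)
  get ± `lfc_scale` (default 3) log2 shifts in group B; their baselines
  are drawn from the expressed range (log2 ~ N(4.5, 1)) because the ε = 1
  pseudocount floors the measurable fold change of near-silent genes — a
  property of FPKM fold changes, not of the test. Three special genes are
  coupled to the standardised per-sample global methylation through a
  Gaussian copula at rank coupling ±0.9: a DNMT3A-like regulator
  (positive), a UHRF2-like regulator (negative), and the CD274 anchor
  (negative — automatically higher in the hypomethylated group).
- **Coupled genes**: eight genes additionally receive strong gene-body
  hypomethylation (−0.4 on their body fragments) together with a forced
  down-shift in expression, planting the body-hypo/down integration
  signature so the DMF × DEG join has recoverable ground truth.

One seed governs everything through named per-stage child streams
(`SeedSequence.spawn`), so stages can be regenerated independently and the
whole bundle is bit-reproducible; the determinism is asserted
byte-for-byte in the tests.

**What the generator does not model** — and hence what passing recovery
tests do and do not show about real data: no raw reads, alignment or
bisulfite-conversion error; no SNPs, copy-number change or tumour purity;
no batch effects or GC/coverage bias; repeat sequences are annotation
intervals, not actual repetitive sequence (no mappability issues);
expression noise is homoscedastic log-normal rather than count-based.
Recovery results therefore validate the statistical machinery under its
own assumptions, not robustness to the full messiness of sequencing data.

## Problem sizes used in validation

The bundled test suite and the acceptance script run on two 500 kb
chromosomes (~5,000 fragments after size selection), 2,000-fragment
direct statistical simulations, 2,000–5,000-gene expression matrices and
100-replicate correlation studies — sizes chosen so the complete
validation runs in a few minutes on one CPU while leaving the recovery
margins (recall ≥ 0.9, calibration bands ±0.01–0.02) comfortably
resolvable.

## Known limitations

- The F test is unweighted by default; for very uneven coverage the
  weighted variant is likely preferable but has no small-sample exactness
  guarantee either.
- BH controls FDR under independence/PRDS; neighbouring fragments are
  spatially correlated in real methylomes, which BH does not model.
- Fragment classification by precedence discards secondary contexts
  (a promoter-overlapping fragment's intronic residue is not counted
  anywhere); the per-gene integration view compensates where it matters.
- The exact-permutation Spearman p enumerates n! permutations and is
  only engaged below n = 10.
- `StudyDesign` is strictly two-group; covariates and paired designs
  beyond the signed-rank flag are out of scope.
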