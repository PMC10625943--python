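# Methods

This note documents the models behind each analysis stage, the tunable
parameters and their defaults, what the synthetic-study generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates, gene units, and TSS windows

All internal coordinates are 0-based half-open; GTF (1-based closed) is
converted at the I/O boundary, BED is taken as-is. Each transcript is one
analysis unit; transcripts sharing a `(chrom, strand, TSS)` triple can be
merged into one unit (`merge_same_tss`), whose expression is the **sum**
of its members (configurable to `max`). Summation was chosen because it
preserves total signal when several isoform records describe the same
promoter.

The TSS window spans `upstream` bp 5′ of the TSS through `downstream` bp
3′ of it, strand-aware, with the TSS base at offset 0 included; the
default −200…+400 bp window therefore covers offsets `[-200, +400)` and
has length 600 on both strands (on the minus strand "upstream" extends to
larger genomic coordinates). The promoter region is `[TSS−1500, TSS)`
strand-aware and excludes the TSS base (half-open); 1500 bp matches the
lower bound of the correlation scan range and is configurable.

WGBS tables that report CpGs on both strands are collapsed onto the plus
strand position of the CpG dyad (minus-strand position − 1) before
counting, making pooled counts strand-symmetric.

## Methylation ratios and the hypo/hyper split

The per-CpG methylation ratio is the pooled `sum(n_meth)/sum(n_total)`
across a tissue's replicates, treated as missing below `min_coverage = 5`
pooled reads (a conventional floor that prevents coverage-1 sites from
contributing 0/1 ratios). Gene-level promoter
methylation is the unweighted mean of pooled per-CpG ratios inside the
TSS window.

The pooled window ratios of **both** tissues form one sample that is split
into hypo- and hypermethylated genes by a single global Otsu threshold
(one shared dotted line across both tissues' distributions; thresholding
per tissue is the documented alternative). Otsu is computed on the exact
sample — candidate thresholds are midpoints between consecutive sorted
unique values, the maximizer of the between-class variance
`w0·w1·(μ0−μ1)²` is returned, ties broken toward the smaller threshold —
rather than on a 256-bin histogram, for exactness and determinism. The
boundary rule is `ratio ≥ threshold ⇒ hyper` (arbitrary but fixed).

Bimodality is assessed with Silverman's critical-bandwidth bootstrap: the
critical bandwidth `h_k` is the smallest Gaussian-kernel bandwidth at
which the KDE has ≤ k modes (geometric bisection, relative tolerance
10⁻³); the p-value is the fraction of B variance-rescaled smoothed
bootstrap resamples whose KDE at `h_k` still shows more than k modes.
Mode counting uses a binned KDE (histogram + Gaussian convolution) on a
512-point grid extended 3·h beyond the data range; the grid size is
configurable. Defaults: B = 200, seeded.

## Correlation analyses

Expression deciles are ten equal-size rank bins of per-gene expression
(log2(TPM+1) of the replicate-mean TPM); the reported statistic is the
Spearman correlation (mid-ranks, t-approximation p-value) between per-gene
expression and the per-gene region mean ratio. The sliding-window scan
computes the same Spearman statistic per 100-bp strand-aware bin from
−1500 to +2000 bp, over genes with ≥ 1 covered CpG in the bin, and
reports the bin minimizing ρ and the longest contiguous run of bins with
ρ < 0 and p < 10⁻³. The methylation/expression fold-change correlation is
the Pearson r between `log2(TPM_liver/TPM_muscle)` and
`log2(ratio_liver/ratio_muscle)` over DEGs with positive window ratios in
both tissues.

## Differential methylation (DMCpGs and DMGs)

Per CpG, replicate-level counts are modelled beta-binomially:
`m_ir ~ BetaBin(n_ir, μ_i, s)` with precision `s` (counts are binomial
with success probability drawn from `Beta(μs, (1−μ)s)`). The test is a
likelihood ratio of tissue-specific means against a shared mean, p-values
from χ²(1).

Two numerical decisions matter:

- **Dispersion is estimated globally by a moment estimator**, not by
  profile/plug-in ML. The intraclass correlation ρ = 1/(1+s) is solved
  from `E[var of replicate ratios] = μ(1−μ)(ρ + (1−ρ)E[1/n])` pooled over
  all tested sites and both tissues. With 3 replicates per tissue,
  per-site ML of the nuisance means biases the dispersion towards zero
  (a Neyman–Scott effect; in simulation the ML plug-in estimate of s was
  ~18× too large), which would make the χ² reference anticonservative —
  with the moment estimator the null p-values are uniform to KS < 0.01 at
  the default replicate structure.
- **Per-site means are profiled by vectorized golden-section search**
  (40 iterations over (0,1)), which keeps the full scan a few seconds for
  ~10⁵ sites on one CPU.

With a single replicate per tissue the test falls back to Fisher's exact
test on the pooled 2×2 counts. Sites below `min_coverage` in either
tissue are recorded untested. Storey q-values are computed over tested
sites only; DMCpGs are q < 0.01, direction = tissue with the lower pooled
ratio.

A gene is a liver DMG iff (a) its window state is hypo in ≥ 1 tissue,
(b) ≥ 1 DMCpG with direction liver-hypo lies inside the strand-aware TSS
window, and (c) the liver window mean is below the muscle one; muscle
symmetric; everything else is non-DMG. Condition (c) resolves conflicting
DMCpG directions, which the single-DMCpG rule alone would leave ambiguous.
The hypo-in-≥1-tissue restriction is applied before labelling.

## Differential expression (DEGs)

Genes are expressed when their count is positive in ≥ 6 of 11 replicates
in either tissue ("reads are present" is read as count > 0; a CPM floor
would be the alternative). The two-group test on expressed genes uses:
median-of-ratios size factors (invariant to rescaling any library by a
constant); per-gene method-of-moments NB dispersions shrunk toward a
fitted `a/μ + b` trend with a prior weight of 10 df; a likelihood-ratio
numerator with means fitted by damped Newton at fixed dispersion; and a
quasi-likelihood F reference whose denominator is the per-gene deviance
dispersion squeezed by empirical Bayes (moment matching on log s²). The
dispersion floor is 10⁻⁴ so that `gammaln(y + 1/φ)` differences remain
numerically accurate. q-values are Benjamini–Hochberg; DEGs are q < 0.01
with the label from the fold-change sign. log2 fold changes are reported
with a 0.5 pseudo-count; the test itself uses raw counts.

This is an in-repo equivalent of the standard count-based NB tests;
parity is claimed at the level of operating characteristics (null FDR
control, power on planted effects), not per-gene p-value identity with
any external tool.

## Proteome (DEPs and DRPs)

A protein is detected in a tissue when its intensity is present in ≥ 3 of
5 replicates. Proteins detected in both tissues are normalized with
`h(x) = γ·arcsinh(a + b·x)`, whose parameters are fitted by profile ML
under the model `h(x_ik) ~ N(m_i, 1)`: the per-protein means and γ are
profiled in closed form, `(a, b)` are optimized by Nelder–Mead on the
profile objective (quadratic term plus the Jacobian `Σ log h'(x)`), and a
least-trimmed-squares loop (trim fraction 10%, 3 iterations) refits on
the proteins with the smallest transformed residual mean squares.
Because the unit-variance convention makes γ absorb the noise scale, the
reported γ corrects the naive `n/SS` estimate for the df consumed by the
per-protein means and for the downward bias of trimmed scale estimation
(a χ² partial-expectation consistency factor). γ is identifiable only
when part of the intensity range probes the arcsinh knee; for data lying
entirely in the logarithmic regime the likelihood is flat in `b` (the
transform degenerates to a log), which is inherent to the model, not a
fitting failure.

Differential abundance uses a moderated t: per-protein pooled variances
(missing replicates dropped) are squeezed toward a moment-matched prior
`(s0², d0)`; with `prior_df = 0` the statistic reduces to the ordinary
pooled two-sample t. q is Benjamini–Hochberg; q < 0.01 gives
liver/muscle-dominant labels by sign; single-tissue proteins are
`*_only` DEPs without testing; intensities are never imputed.

The protein/mRNA ratio is `log(mean intensity / mean TPM)` per tissue,
missing when the protein is undetected or TPM ≤ 0 (the quantity is
direction-symmetric: flipping it globally only swaps DRP labels). The
liver ratio is regressed on the muscle ratio by OLS over all proteins
with both ratios; for each protein the line is refitted without it and
the protein is a DRP when the refit's MSE on the remaining n−1 points is
strictly below the full-fit MSE on all n points — the most literal
reading of "the MSE decreases even slightly". The alternative reading
(refit evaluated on all n points) is available behind
`compare_to="refit_all"` but can never flag anything, since the full OLS
fit already minimizes the SSE over all points. Flagging is one-pass, not
remove-and-repeat. An exactly collinear cloud (MSE ≈ 0 to machine
precision) yields no DRPs. Note the criterion is scale-free — the flag
threshold is ≈ √MSE_full — so the flagged fraction depends on the shape,
not the scale, of the residual distribution: with planted outliers
inflating MSE_full the bulk is rarely flagged, while under an exactly
Gaussian null ~32% of points would be (P(χ²₁ > 1)); this is a property of
the published criterion itself.

## TF binding and DTGs

A TF is bound to a gene when any of its peaks intersects the
strand-agnostic flank `[TSS−1000, TSS+1000)`; multiple peaks collapse to
one flag, and the per-gene state is the set of bound TFs per tissue.
Expression effects are tested on log2(TPM+1) over (gene, tissue)
observations in two families, each Storey-corrected separately: per-TF
marginal tests (bound vs unbound) and Welch tests between every pair of
observed states; groups below 3 observations are skipped and recorded.
A gene whose states differ between tissues is a DTG when its own state
pair is significant (`direct_test`) or when the symmetric difference of
its states consists only of individually significant TFs
(`combination_inference`); identical states are never DTGs. Both test
families are emitted for inspection because the published description of
which state pairs were tested is compressed; the calls use them exactly
as stated above.

Histone-mark consistency across replicate peak files requires a gene to
be peaked in all provided files per mark per tissue by default
(`min_files` configurable). ATAC/histone/CpG-island overlaps with gene
classes are right-tailed Fisher tests for enrichment and left-tailed for
depletion.

## Integration

Transcript and protein calls are collapsed to gene IDs; contradictory
directional labels within one gene become `conflict` and are excluded
from directional overlaps. Composites require direction agreement at
every level: DM-DEG = DMG ∩ DEG (same tissue), DM-DEP = DM-DEG ∩ DEP,
DR-DEP = DRP ∩ DEP, DT-DEP = DTG ∩ DEG ∩ DEP. Cross-direction overlaps
are tested as depletion (left tail). Requiring the direction match at all
three levels for DM-DEP is the stricter of the two defensible readings;
the flags are plain set algebra and are verified against independently
computed set intersections at run time in the test suite.

CpG-density vectors count CpGs in fifteen 40-bp strand-aware bins across
the 600-bp TSS window; Ward clustering (Euclidean distance, variance-
minimizing linkage, tree cut at k = 2) splits genes into low/high density
classes named by mean total count. Gene-set enrichment is a right-tailed
Fisher test per set against the measured background universe
(proteome-level background for protein-derived lists, transcriptome-level
for gene lists), BH-corrected across sets, grouped by a user-supplied
set→category map.

## Multiple-testing machinery

Storey q-values estimate π₀ on a λ-grid (0.05…0.95, step 0.05) with a
cubic-polynomial smoother extrapolated to λ = 1, clipped to (0, 1]; below
100 p-values the smoother is unstable and a fixed λ = 0.5 estimate is
used. `q_i = min over p_j ≥ p_i of π₀·n·p_j/rank(p_j)`; with π₀ = 1 this
reduces exactly to BH, and Storey q ≤ BH q always holds here since π₀ is
clipped at 1.

## The synthetic study

`tissuedom.simulate` generates the study the pipeline assumes, with all
planted labels recorded in the TruthTable. Default conditions (the
"default bundle"): 2,000 genes on 4 chromosomes; 10% + 10% DMGs with
window means 0.10 vs 0.80 (separation 0.7); beta-binomial counts with
precision s = 1/0.02 = 50 at 30× Poisson coverage, 3 replicates/tissue;
methylation→expression coupling with probability 0.8 and a +2 log2 shift
(4-fold) in the hypomethylated tissue; negative-binomial counts
(dispersion 0.1, 11 replicates/tissue, ±15% log-normal library factors);
10% DRPs with a log 3 (3-fold) protein-only shift and 4% per tissue
"tissue-absent" proteins, 5 replicates/tissue with 5% dropout and 20%
replicate CV (log-sd 0.20); 10% DTGs bound by one of 3 TFs in exactly one
tissue with a +2 log2 expression effect, plus 5% background genes bound
in both tissues; CpG densities Poisson(10) for the low class (all DMGs
and 10% of the rest) and Poisson(47) for the high class, 8 flank CpGs
per gene and 5 non-CpG cytosines with mean ratio 0.02.

Structural choices worth knowing:

- The per-gene window-ratio jitter (sd 0.03) is **shared between
  tissues**, so non-DMG genes are genuinely null for the differential
  test; flank CpG states are drawn independently per (gene, tissue) and
  independently of expression, so the scan's anticorrelation is confined
  to the planted window.
- Genes hypomethylated in both tissues get a +1.5 log2 ubiquitous
  expression bonus in both tissues — this produces the negative
  methylation–expression correlation across genes without creating
  differential expression.
- Protein log-intensity couples to the log of the tissue's **measured**
  mean TPM (slope 1), plus a per-gene translation offset (sd 0.8) common
  to both tissues. Coupling to the realized mRNA is the biologically
  coherent reading (protein tracks the cohort's actual transcript
  levels) and keeps the RNA cohort-sampling noise out of every null
  protein's protein/mRNA ratio; with a latent-mean coupling that noise
  (≈ √(0.1/11) per tissue) would dominate the scale-free DRP criterion's
  null behaviour.
- One protein per gene; gene lengths are fixed at 1 kb and TPM is
  count-rate normalized to 10⁶, since TPM only enters ratios and ranks.

What the generator does **not** emulate: spatial autocorrelation of
methylation along chromosomes beyond the gene window, read-level data
(FASTQ), isoform structure, batch effects, intensity-dependent proteomic
dropout, and correlated TF binding. Passing recovery tests therefore
shows the estimators are correct under the stated model, not that the
pipeline is robust to artefacts these features create in real data.

Determinism: every stage draws from its own `default_rng([seed, stage])`
stream; identical configurations produce byte-identical output files.

## Problem sizes used in the checks

The bundled test-suite and the acceptance script run the full pipeline on
the 2,000-gene default bundle (~100k cytosines) and use 200–400-gene
bundles for repeated-seed properties (scan localization over 20 seeds,
null calibration of each test family over 20 seeds at 400–1,500 units
each); the tiny 200-gene bundle drives the end-to-end determinism check.
These sizes were chosen so the statistical assertions are
well-powered while a complete run stays in tens of seconds on one CPU.

## Known limitations

- The beta-binomial test assumes one global dispersion; strongly
  site-variable dispersion in real data would degrade calibration.
- The QL F-test's dispersion trend is a two-parameter `a/μ + b` fit, not
  a spline; extreme mean-dispersion shapes are approximated coarsely.
- VSN fits a single `(a, b)` for all samples rather than per-sample
  affine parameters, which is adequate after iBAQ-style normalization
  but would not correct strong per-run intensity distortions.
- The DTG combination rule treats per-TF marginal significance as
  evidence for any state difference composed of those TFs; correlated
  binding could make this rule anticonservative.
- The DRP leave-one-out criterion is threshold-free by design and
  inherits the sensitivity to residual-distribution shape described
  above.
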