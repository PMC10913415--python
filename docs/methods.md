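# Methods

`loyscan` detects mosaic loss of chromosome Y (LOY) in single cells from
UMI count data and quantifies LOY enrichment across leukocyte subtypes.
This note documents the model behind each stage, the parameters that
matter, what the synthetic cohorts do and do not emulate, and the
numerical choices made where the design was open.

## LOY calling

A male cell that has lost its Y chromosome cannot transcribe genes in the
male-specific region of the Y (MSY); genes in the pseudoautosomal region
(PAR, e.g. *CD99*) are shared with the X and keep one expressed copy, so
they are never counted as MSY evidence. Two rules are provided.

**Zero rule.** A male cell is LOY iff its total MSY count over all
requested count layers is exactly zero. Spliced, unspliced and ambiguous
transcript counts all contribute — intronic reads rescue cells whose
exonic MSY reads dropped out, which is what makes the rule usable at
droplet depth. Sensitivity is 1 by construction (a Y-less cell has no
template); specificity is limited by dropout: a normal cell is falsely
called LOY with probability `∏_g (1 + d·μ_g/θ)^(−θ)` under the
negative-binomial expression model with per-cell depth `d`, MSY gene means
`μ_g` and dispersion `θ`. The rule should only be used when that product
is small; the cluster MSY score (below) is the practical check.

**Female-background threshold rule.** In noisier data, cells from female
donors show nonzero MSY signal (index hopping, ambient RNA,
mismapping). Treating female MSY expression as the technical null, the
threshold is the 95th linear-interpolation quantile of total MSY
expression among female cells *with any MSY expression*; a male cell is
LOY iff its MSY expression is strictly below that threshold **and** it
expresses at most one MSY gene (genuine Y-bearing cells typically express
several MSY genes, background usually hits one). Quantile type is linear
interpolation between order statistics, the default of mainstream
statistical software; strictness follows the rule's wording exactly
("less than", "one or less").

*Units.* Estimation and calling must use the same units. Raw summed
counts are the default; `units="normalized"` uses counts per 10,000
library reads. The quantile's guarantee — at most `5% + 1/n` of the
estimation cells lie at or above the threshold — holds only when values
are effectively continuous: on small tied integers the threshold can sit
on an atom of the distribution and the at-or-above mass exceeds 5%. Deep
libraries (the regime the rule targets; the public T-cell datasets carry
10^5–10^6 UMIs per cell) make normalized values effectively tie-free,
which is why the calibration checks run in normalized units on a
deep-library synthetic cohort. On a genuinely held-out female sample the
exceedance is a random quantity centred near 5% (sd ≈ 0.22/√n), so
held-out checks use a Monte-Carlo margin rather than the constructional
bound.

**Cluster MSY adequacy score.** Per cluster,
`score = 100 × mean_cells(total_msy / library_size × 10,000)`, with a
default pass threshold of 250. The score quantifies whether a cluster
expresses enough MSY for LOY calls to be trustworthy; clusters failing it
are flagged (default) or excluded from fraction tables. The functional
form — library-normalized per-cell MSY expression averaged per cluster,
scaled so the conventional 250 cutoff is meaningful — is this package's
own definition; both the scale and the cutoff are configurable, and the
score should be treated as a relative diagnostic rather than a calibrated
quantity.

## Quality control and sex inference

Cells are filtered on expressed features (genes with any count, over the
summed layers), mitochondrial read percentage and/or total UMIs. All
bounds are strict (a cell with exactly 500 features fails `min_features =
500`; exactly 13% mitochondrial fails `max_mito_pct = 13`), the literal
reading of "more than / less than" thresholds. Filtering is idempotent
and every removed cell is attributed to at least one named criterion.

Donor sex, when absent from metadata, is inferred per sample: male iff
the fraction of cells with any MSY expression strictly exceeds 0.5. A
fraction exactly at the cutoff calls female with a warning — ambient
contamination can only inflate the fraction, so the conservative
tie-break is female.

## Cluster annotation

Clusters (supplied, not computed — clustering is upstream of this
package) are labelled by an ordered marker-rule panel: Tregs by
CD4/FOXP3/IL2RA/TIGIT (split into CTLA4+/− states), naïve CD4 T by
CD4/FHIT/CCR7 with FHIT/CCR7-negative CD4 cells as helper T, cytotoxic T
by CD8A (the panel uses CD8A for "CD8"), NK by NKG7/GNLY, monocytes by
FCN1/CD14 with FCGR3A separating non-classical, B cells by CD19/VPREB3.
Clusters matching no rule are "unidentified". "High" is defined
reproducibly: a marker is high in a cluster when the cluster's mean
normalized log expression (`log1p` of counts per 10,000) exceeds the mean
of that marker's per-cluster means. This replaces manual curation with a
deterministic rule; it presumes the panel's populations are actually
present so that the across-cluster mean separates high from low.

## Statistics

All tests are implemented in this package (scipy/statsmodels serve only
as cross-checks in the test suite).

* **Wilcoxon signed-rank** — zero differences dropped; with ≤ 25 untied
  absolute differences the p-value is exact via the generating-function
  distribution of the rank sum (identical to enumerating all 2^n sign
  vectors); otherwise a normal approximation with mid-ranks,
  tie-corrected variance and continuity correction.
* **Theil–Sen regression** — slope is the median of all pairwise slopes
  (equal-x pairs excluded), intercept the median of `y − slope·x`; the
  Siegel repeated-median variant is available. The p-value is a
  one-sample signed-rank test of the pairwise slopes against zero,
  mirroring the summary of median-based linear model packages. Pairwise
  slopes are not independent, so this p-value is anticonservative under
  the null (simulations here show ~20% rejection at the nominal 5% level
  on small cohorts) — a known property of that summary, kept for
  comparability; treat it as a descriptive score and use the paired
  Wilcoxon or the GLM for calibrated inference.
* **GLMs** — logit-link binomial/quasibinomial and log-link negative
  binomial fitted by IRLS to a relative deviance change below 1e-8
  (max 100 iterations). Quasibinomial dispersion is Pearson χ²/df. The NB
  size θ is estimated by damped Newton steps on the profile score,
  alternating with IRLS to joint convergence (matching ML estimation as
  in `MASS::glm.nb`). Coefficients with |β| > 15 on the link scale raise
  a separation warning. Factors are coded with sum-to-zero contrasts.
* **Type-3 tests** — each term is tested by refitting without that term's
  columns while all other terms, including interactions, remain; the
  statistic is the deviance difference (divided by the full-model φ̂ for
  quasi families, with θ held at the full-model estimate for NB) referred
  to χ² at the term's column count. Under sum contrasts this is invariant
  to factor-level and term ordering. Referring quasi-family statistics to
  χ² (rather than F) follows the reporting convention of LR statistics
  for such models; F-referencing can be derived from the returned
  dispersion and degrees of freedom.
* **Treg abundance analysis** — per sample: Treg LOY%, LOY% pooled over
  the other T-cell types (cell-weighted by default; type-averaged
  pooling available), and the Treg share of CD4+ cells. Outputs the
  Theil–Sen fit of Treg share on Treg LOY%, the paired Wilcoxon of Treg
  vs other-T LOY%, and a quasibinomial type-3 test of Treg share on Treg
  LOY%.

## Synthetic cohorts

The generator emulates a PBMC-like multi-sample cohort: cell types drawn
per sample from configurable proportions; gene counts negative-binomial
(gamma–Poisson, variance `μ + μ²/θ`, default θ = 10) with a per-cell
log-normal depth multiplier (default σ = 0.35); a fixed Bernoulli split
of each gene's counts into spliced/unspliced layers (default 25%
unspliced); per-cell mitochondrial read share drawn from Beta(2, 30).
LOY is genotype: true-LOY cells have all MSY rates zeroed and PAR rates
halved (one copy lost); female cells have MSY rates zero always. Default
cohort: 20 male + 4 female samples, 600 cells each; Treg LOY 18% vs 3% in
other T cells, 15% in NK and 12% in monocytes; expected MSY output ≈ 7
UMIs per normal male cell at unit depth (RPS4Y1 dominant), giving a
zero-rule false-positive probability well below 1% over the depth
distribution. Marker genes are elevated 8× over a 0.25 baseline in their
designated types.

Per-sample LOY propensity varies on the logit scale (sd 0.5), and the
Treg share of a sample is coupled to its realized Treg LOY level
(multiplier `1 + 0.8·(f_s − f̄)/f̄`), giving the abundance analyses a known
positive generative sign to recover.

Ambient MSY contamination adds Poisson(rate) MSY UMIs per cell
(genotype-independent), allocated across MSY genes proportionally to
their means — concentrating background on the dominant MSY gene, a
modelling choice exposed as a parameter. The draws are realized from a
fixed per-cell arrival stream, so for a fixed seed a higher rate strictly
adds contamination on top of a lower rate: sweeps are monotone cell by
cell and the zero rule's anti-monotonicity is exact, not statistical.
Zero-rule sensitivity under contamination decays as `exp(−rate)` (the
probability a true-LOY cell receives no ambient MSY read).

**What the cohorts do not emulate:** batch effects, doublets, cell-cycle
structure, tumour microenvironments, realistic transcriptome size
(default 120 genes; the deep public-style regime uses 2,000), empirical
marker co-expression structure, or read-level artefacts. Passing tests
demonstrate correctness of the rules and statistics under the stated
generative model, not calibration on any particular real dataset.

**Problem sizes.** The checked-in verification suite uses cohorts of
3,000–20,000 cells and 120–2,000 genes, 200–1,000 resampling replicates
for the enumeration/uniformity checks, and completes in well under a
minute per stage; all larger analyses scale linearly in cells × genes.

## Known limitations

* The cluster MSY score's functional form is this package's own; scores
  are comparable within a dataset, not across normalization schemes.
* The packaged MSY/PAR gene list is frozen (nine canonical expressed MSY
  genes, CD99, five mitochondrial transcripts); annotations derived from
  a full gene model may differ in minor membership and should be supplied
  explicitly for real data.
* The threshold rule assumes the female MSY background is exchangeable
  with male technical noise; sorting or dataset-specific artefacts that
  differ by sex violate this.
* Exact Wilcoxon p-values require untied absolute differences; LOY
  percentages with many identical values fall back to the approximate
  path.
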