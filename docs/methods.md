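# Methods

This note documents the models, estimators, numerical choices and known
limitations of each stage of the pipeline, and what the synthetic-data
generators do and do not emulate.

## Substitution model and likelihood engine

**Model.**  HKY85: stationary base frequencies π and a
transition/transversion rate ratio κ.  The generator matrix is normalized
so one unit of branch length equals one expected substitution per site at
stationarity; branch lengths are therefore in substitutions/site, and the
screen's tree carries the genome-wide rates at fourfold-degenerate coding
sites.  Transition probabilities are computed from a symmetric
eigendecomposition (reversibility makes `diag(√π) Q diag(1/√π)`
symmetric), which guarantees row sums of 1 and detailed balance to
round-off and lets P(t) for all branches be produced from one `eigh`
call.  Base frequencies with a zero entry are rejected explicitly rather
than perturbed.

**Likelihood.**  Felsenstein pruning over the unrooted 4-taxon topology
((cerevisiae,paradoxus),mikatae,bayanus), represented rooted at its
internal trifurcation (5 branches; by reversibility the root placement is
immaterial).  Site patterns are compressed before traversal.  Gaps and
ambiguity codes are missing data — a partial-likelihood vector of ones at
the tip — not column deletions, so the locus length used by the indel
filter is preserved.  An all-gap column contributes likelihood 1.

**Base frequencies and κ.**  π is taken as empirical counts over the
locus (gaps excluded), which removes three free parameters per locus; κ
is ML-estimated once per locus under the constrained model and held fixed
in the unconstrained fit so the LRT isolates rate heterogeneity.  A
per-locus κ (rather than one global value) is the default because locus
alignments are long enough (hundreds of sites) for a stable estimate and
it makes loci independent units; nothing else in the pipeline depends on
the choice.

**Branch lengths on fourfold sites.**  A codon column enters the
fourfold-degenerate set only when every taxon's codon is gap-free and
fourfold-degenerate at its third position under the standard genetic
code.  Branch lengths (and optionally κ) are optimized jointly by
L-BFGS-B on log scale, bounds [1e-8, 20] substitutions/site; the fit is
returned with a convergence flag rather than failing silently.

## Rate-heterogeneity screen

The constrained model has one shared dNC/dS multiplier r applied to every
branch (effective length r·L_b); the unconstrained model has one r_b per
branch, so the LRT has 5 − 1 = 4 degrees of freedom.  Ratios are bounded
to [1e-6, 100] and fit on log scale with multi-starts at 0.1, 1, 10
(ratio likelihoods can be flat near zero); the unconstrained optimization
additionally starts from the constrained optimum, which enforces the
nesting inequality up to optimizer tolerance (1e-10 relative on the
objective).  p-values come from the χ²(4) upper tail; the genome-wide
screen compares each p to α divided by the number of loci actually tested
after the indel filter.

**Indel filter.**  The "length of insertions/deletions" is counted as the
number of alignment columns in which at least one taxon has a gap, making
the fraction commensurate with alignment length; the 15% boundary is
strict (exactly 15% is kept).  An allowlist retains named loci despite the
filter, mirroring the practice of carrying forward a candidate whose
analysis began before filtering; allowlisted loci still count toward the
Bonferroni denominator.

**Calibration.**  Under constrained-model simulation at 1 kb the LRT's
empirical type-I error at nominal 0.05 sits inside the exact binomial 99%
interval over 500 replicates (acceptance suite), and the p-value
distribution is uniform by KS test.  A 5× multiplier on one branch of a
2-kb locus is recovered as the largest estimated ratio in ≥95% of
replicates.

## Pairwise dN/dS scan

Nei–Gojobori (1986) counting: expected synonymous sites per codon are the
fraction of the nine single-base changes that preserve the amino acid,
averaged across the two sequences; observed differences between codons
differing at k positions are averaged with equal weights over all k!
orderings of single-base steps.  A change to or from a stop codon is
classified nonsynonymous (a stop is not an amino acid), which preserves
the identity S + N = 3 per compared codon; codon pairs containing gaps,
ambiguity, or a stop codon are skipped pairwise and internal stops raise
a warning.  Multiple hits are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3), reported as saturated (NaN) when p ≥ 3/4.
ω is undefined (NaN), never infinite, when dS = 0.

Windows default to 150 codons advanced by 25 (the window geometry of the
original scan is not recorded anywhere authoritative; both are
configurable), and the final window is anchored at the 3′ end so the scan
tiles the gene.  The whole-gene estimate pools sites and differences —
it is not a mean of window ratios.

**Monte-Carlo intervals.**  A parametric bootstrap in the spirit of
K-estimator: synonymous and nonsynonymous difference counts are
resimulated as binomials over the (rounded) estimated site counts at the
Jukes–Cantor-inverted per-site difference probabilities, re-estimated,
and the empirical 2.5/97.5 percentiles taken.  The interval is
deterministic given its seed.  This counting-level bootstrap is
approximate — it resamples the NG86 summary rather than codon evolution —
and is documented as such; empirical coverage of the true ω in the test
suite is close to nominal (checked at 150 meta-replicates with a binomial
tolerance band).

## Growth-delay phenotype

The resistance phenotype is t_maxrate(sulfite) − t_maxrate(control),
where t_maxrate is the time of the peak smoothed derivative of log OD.
Numerically: log OD is smoothed by a centered moving average
(`smooth_window`, default 5 points); the derivative is taken by central
differences spanning the smoothing half-width (differencing adjacent
points of a smoothed series amplifies high-frequency noise); the rate
series is then smoothed again (`rate_smooth_window`, default 9 points)
before the peak is located, ties breaking to the earliest time.  All
windows are symmetric, so the landmark is exact on noiseless curves,
exactly equivariant under time shifts, and invariant to affine rescaling
of OD.  A culture whose total log-OD increase is under one doubling is a
non-grower; delays involving one are reported missing with a reason code
("control_failed"/"sulfite_failed") rather than a number, since some
strains grow in water but not sulfite.

Day-to-day shifts are removed by per-day Z-scoring with the sample
standard deviation (n−1); a day with fewer than two values or zero
variance is an error naming the day.  Z-scoring is idempotent.
Group-level inference is nonparametric: Kruskal–Wallis (tie-corrected,
χ²(k−1) tail; H = 0 and p = 1 when all values are identical) and pairwise
Wilcoxon rank-sum tests, exact for groups of ≤10 without ties and a
tie-corrected normal approximation otherwise, Bonferroni-adjusted as
min(1, m·p).

## Chimeric-allele decomposition

Delays of the 22-construct panel (both parents, five single-region
reciprocal swaps, five pairwise reciprocal swaps) are fit with a linear
mixed model with a per-plate (batch) random intercept, by maximum
likelihood — not REML, because the two models differ in fixed effects and
are compared by an LRT.  Parameter counting follows the convention
intercept + 5 regions + 2 variance components = 8 for the additive model
and + 10 pairwise interactions = 18 for the epistatic model, hence 10 df.
Day effects are handled by prior Z-scoring, not by the model.

The fit profiles the variance ratio λ = σ²_batch/σ²_resid: given λ, the
GLS coefficients, profiled σ² and log-likelihood are closed-form (a
Woodbury identity per batch block); λ is scanned on a log grid from
e⁻³⁰ to e⁸ (41 points plus an effectively-zero point) and polished with
bounded scalar minimization (xatol 1e-10).  At λ = 0 the fit reduces
exactly to OLS.  The implementation is cross-checked against
`statsmodels` `MixedLM(reml=False)` in the test suite (agreement in lnL
and coefficients to ≤1e-4), which serves as oracle only.  Fixed-effect
p-values are two-sided Wald tests on the ML covariance; with ~66
observations these are mildly anticonservative relative to t-based
small-sample corrections, which is why the permutation check below
exists.

Variance explained against the intercept-only null (random intercept
retained) is R² = 1 − exp(−LR/n).  Percent contributions are
100·|effect_i|/|total difference|, with the parent-allele difference an
explicit input (the sum of additive effects need not equal the observed
parent difference when epistasis is present, so the two are deliberately
not conflated); percents need not sum to 100.

**Permutation check.**  Construct labels (the full 5-region design row)
are permuted within day, the additive model refit, and the pooled region
Wald p-values compared to Uniform(0,1) by KS distance — the check that
parametric mixed-model p-values are not misbehaving on a given dataset.
Deterministic given its seed.

## Expression analysis

**qPCR.**  Relative expression is 2^−(Ct_target − Ct_reference) against
the reference gene.  For allele-specific primer pairs a plate factor —
the apparent allele ratio measured on heterozygous genomic DNA, whose
true ratio is 1:1 — divides the reference-species-primer measurements, so
primer-efficiency bias cancels; amplification efficiency is assumed 2
after correction.  Values are then mean-normalized for day and batch on
the log scale.  Missing reference Cts or a missing plate calibration are
errors, not imputations.

**Per-gene ANOVA.**  Expression values are analyzed as gene-level log2
quantities after per-array median centering.  The first-level model is
`expression = allele*time + technical replicate + error`; F-tests are
computed by nested least-squares model comparisons vectorized across all
genes, with the error mean square taken from the full model (equivalent
to classical ANOVA in this balanced design; verified against
`statsmodels.anova_lm` to 1e-10 on single genes).  A gene with identical
values everywhere gets F = 0, p = 1; an incomplete design cell is an
error.  Genes significant at the first level get the second-level model
`expression = noncoding*coding + error` (with time interactions for genes
whose first-level signal is the allele×time interaction), and the effect
source label (coding / noncoding / interaction) is the significant term
with the smallest p — a classification invariant to which species is
called reference.

**Permutation FDR.**  Allele labels are permuted at the biological-sample
level (technical replicates stay attached): within time-point for the
allele main-effect test, across all samples for the interaction test.
FDR = mean permuted significant count / observed count, reported even
above 1 (capped only at the report layer) and undefined when nothing is
observed.  Deterministic given its seed.  Note that parametric F
p-values are exactly uniform under relabeling only for null genes;
permuting the labels of a strongly bimodal (spiked) gene leaves residual
miscalibration in the parametric tail — the estimator uses permuted
counts, not permuted p-value uniformity, so this does not bias the FDR.

**Fold-change sets.**  "Greater than 2-fold" is strict: |log2 FC| > 1
and p below threshold; exactly 2-fold is excluded, and the up/down sets
are disjoint by construction.

## Synthetic-data generators

All generators are pure functions of their arguments including the seed;
one integer seed fans out to substreams via `SeedSequence.spawn`.  They
deliberately share no algorithmic code with the analysis modules: the
sequence simulator builds its own HKY85 generator matrix and uses
`scipy.linalg.expm`, while the analysis engine uses a symmetric
eigendecomposition, so oracle and implementation are independent paths.

* **Alignments** — i.i.d. sites evolved along the fixed topology with
  per-branch effective lengths L_b·r_b; root states from π.  Optional
  gaps are contiguous runs with geometric lengths (mean 5 columns)
  written into random taxa until a target gapped-column fraction is
  reached; only that fraction matters to the filter under test.  Not
  emulated: rate variation across sites, context effects, alignment
  error — so passing screens here say nothing about alignment-induced
  false positives, which real scans must worry about.
* **Chimera tables** — value = intercept + Σ effects·x + Σ
  interactions·x_i x_j + batch intercept N(0, σ²_b) + N(0, σ²_e), with
  one plate per replicate of the full 22-construct panel and one day per
  plate.  The published five additive effects (−0.251, −1.189, −1.509,
  0.039, 0.012 h against a 3.05 h parent difference) are used as
  simulation truths for recovery tests; the raw phenotype data behind the
  published table are not recomputable, and recovery of the truths is the
  assertion.  The five pairwise swap pairs default to the four adjacent
  pairs plus (1,5); the original breakpoint pairing is not recorded.
* **Growth curves** — log OD follows a logistic rise between a starting
  and final OD (defaults 0.1 → 1.5, consistent with a culture entering a
  plate reader after a 3 h outgrowth) with inflection at the stated time,
  sharpness 1.0 h⁻¹ (peak specific growth rate ≈ 0.68 h⁻¹, exponential
  phase lasting roughly 3.5 h); the sulfite curve is the control
  translated in time, plus i.i.d. Gaussian OD noise.  Not emulated: lag
  phases, diauxic shifts, evaporation drift, well-position effects.
* **Expression matrices** — background genes are N(0, σ²) on the log
  scale; spiked genes add a ±effect/2 pattern keyed to coding origin,
  noncoding origin, their XOR (interaction), time, or coding×time.  Not
  emulated: gene-gene correlation, intensity-dependent variance, probe
  effects — so FDR behavior here reflects an independent-gene ideal.
* **Codon pairs** — starting from a random stop-free sequence, each
  position substitutes to a specific alternative with probability p_s/3
  (synonymous) or p_n/3 (nonsynonymous), p = (3/4)(1 − e^(−4d/3)); stop
  codons are never created.  Unbiased for NG86 recovery at moderate
  divergence (checked at 20k codons).

## Problem sizes in the checks

The acceptance-level checks run at: 200 random instances for the
pruning-vs-enumeration oracle; 500 null loci of 1 kb for LRT type-I
error; 200 loci of 2 kb for 5× multiplier recovery; a 66-observation
panel (and five 30-plate panels, reporting the median batch-variance
estimate, since a single panel's ML variance estimate has sampling sd
≈ 0.26) for chimera recovery; 2,000 genes × 48 samples with 100
permutations for expression calibration and FDR.  Module-level
simulation examples that are not acceptance checks (Monte-Carlo CI
coverage, window localization, noisy-delay accuracy) run at 40–200
replicates with binomial tolerance bands matched to those counts.

## Known limitations

* The screen's LRT relies on χ² asymptotics; at very short loci
  (≲200 bp) the test is conservative and the optimizer's ratio bounds can
  truncate extreme estimates.
* NG86 counting with equal path weights is approximate relative to
  ML codon models and is documented as approximate, not bit-identical,
  to the K-estimator binary it conceptually replaces.
* The delay statistic degrades for cultures whose maximum growth rate
  occurs near the ends of the recording window, and the non-grower
  threshold (one doubling) is a convention.
* Wald p-values from the mixed model ignore small-sample df corrections;
  the permutation check is the guard.
* The second-level expression classification assigns a single source
  label per gene even when several terms are significant (smallest p
  wins); genes with no significant second-level term are "unattributed".
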