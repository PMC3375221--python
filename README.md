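# regdiverge

Screening and functional dissection of regulatory divergence in yeast.

When a promoter accumulates substitutions faster in some lineages than in
others, it is a candidate for functional divergence — by loss of constraint
or positive selection.  `regdiverge` implements the complete quantitative
workflow behind that kind of study in the four-species *Saccharomyces*
system (*S. cerevisiae*, *S. paradoxus*, *S. mikatae*, *S. bayanus*):

1. **Rate-heterogeneity screen** (`phylo_core`, `rate_screen`).  For each
   noncoding locus, the ratio of its substitution rate to the genome-wide
   rate at fourfold-degenerate coding sites, dNC/dS, is fit by maximum
   likelihood under HKY85 on a tree whose branch lengths are the
   fourfold-degenerate rates.  A constrained model (one shared dNC/dS)
   is compared with an unconstrained model (one dNC/dS per branch) by a
   likelihood ratio test, 2Δln L ~ χ²(b−1) with b = 5 branches of the
   unrooted 4-taxon tree.  Loci whose gapped columns exceed 15% of the
   alignment are filtered out (strict inequality, with an explicit
   allowlist override), and the genome-wide screen is Bonferroni-corrected
   over the loci actually tested.
2. **Sliding-window dN/dS** (`codon_scan`).  Pairwise Nei–Gojobori (1986)
   counting with Jukes–Cantor correction, windowed over the coding region,
   with parametric-bootstrap (Monte-Carlo) confidence intervals for dN, dS
   and ω = dN/dS.
3. **Sulfite-resistance phenotyping** (`phenotype`).  The phenotype is the
   sulfite-dependent growth delay: the difference in the time of maximum
   specific growth rate (peak of the smoothed d log OD/dt) between a
   sulfite-treated culture and its water-treated control.  Day effects are
   removed by per-day Z-scoring; groups are compared with Kruskal–Wallis
   and Wilcoxon rank-sum tests with Bonferroni correction.
4. **Chimeric-allele effect decomposition** (`chimera_effects`).  Growth
   delays of 22 chimeric constructs that swap five gene regions between
   two species are fit with linear mixed models (per-plate random
   intercept, ML):  an additive model (8 parameters) and one adding all
   10 pairwise region interactions (18 parameters), compared by an LRT
   with 10 df.  Variance explained is R² = 1 − exp(−LR/n); per-region
   contributions are 100·|effect|/|parent difference|.
5. **Expression analysis** (`expression`).  qPCR relative expression with
   plate-specific correction from heterozygote calibration; genome-scale
   per-gene ANOVA `expression = allele*time + technical replicate + error`
   with a second-level model `expression = noncoding*coding + error`
   attributing allele effects to the coding region, the promoter, or
   their interaction; false-discovery rates by label permutation.
6. **Synthetic data** (`synthetic_data`).  Seeded generators for every
   input above, so the whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from regdiverge import phylo_core as pc, rate_screen as rs
from regdiverge import chimera_effects as ce, synthetic_data as sd

params = pc.HKY85Params(kappa=2.0, pi=np.array([0.3, 0.2, 0.2, 0.3]))
tree = pc.yeast_tree([0.05, 0.10, 0.08, 0.15, 0.20])  # fourfold-site rates

loci = {f"null_{i}": sd.simulate_alignment(tree, params,
            pc.BranchRates.shared(1.0), 1000, seed=i) for i in range(4)}
loci["accelerated"] = sd.simulate_alignment(tree, params,
    pc.BranchRates.free([5, 1, 1, 1, 1]), 2000, seed=99)

report = rs.screen_loci(loci, tree, alpha=0.05)
for r in report.per_locus:
    print(f"{r.locus_id:12s} dNC/dS(cer)={r.branch_ratios[0]:5.2f}  "
          f"2dlnL={r.lrt_stat:7.2f}  p={r.p_value:.2e}  "
          f"significant={r.bonferroni_significant}")
```

```
null_0       dNC/dS(cer)= 0.82  2dlnL=  12.30  p=1.52e-02  significant=False
null_1       dNC/dS(cer)= 1.06  2dlnL=   3.72  p=4.45e-01  significant=False
null_2       dNC/dS(cer)= 0.66  2dlnL=  10.18  p=3.75e-02  significant=False
null_3       dNC/dS(cer)= 1.15  2dlnL=   5.80  p=2.15e-01  significant=False
accelerated  dNC/dS(cer)= 4.60  2dlnL= 346.84  p=8.45e-74  significant=True
```

Only the locus simulated with a 5× rate multiplier on the *S. cerevisiae*
branch survives the Bonferroni-corrected screen (per-test threshold
0.05/5 = 0.01); its estimated branch ratio (4.60) recovers the simulated
acceleration.  Continuing with a chimera panel simulated at the published
effect scale:

```python
table = sd.simulate_chimera_table(
    np.array([-0.251, -1.189, -1.509, 0.039, 0.012]),
    batch_sd=0.3, residual_sd=0.4, reps=3, seed=7)
dec = ce.decompose_effects(table, total_difference=3.05)
print(f"epistasis LRT: 2dlnL={dec.lrt_stat:.2f}, df={dec.df}, p={dec.p_value:.3g}")
print("percent contributions:", np.round(dec.percent_contributions, 1))
```

```
epistasis LRT: 2dlnL=8.73, df=10, p=0.558
percent contributions: [ 7.2 45.7 44.5  4.6  4.6]
```

With purely additive simulated truth the epistasis LRT is (correctly)
non-significant, and the first three regions account for most of the
parent-allele difference, mirroring the scale of the real effect table.

A command-line interface mirrors the library:
`regdiverge screen|dnds|delay|chimera|expr|fourfold|brlens|simulate --help`.

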