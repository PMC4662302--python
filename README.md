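# rangegen

Comparative ecological genetics of rare and widespread congeners.

Closely related species often span orders of magnitude of geographic range
size, and a recurring question in evolutionary ecology and conservation is
which genetic attributes — neutral diversity, quantitative-trait structure,
heritability, phenotypic plasticity — actually track rarity. `rangegen`
implements the full analysis pipeline for that comparison in groups of
selfing plants scored at codominant markers (e.g. montane mustards typed at
a microsatellite panel), together with a synthetic-data generator that
reproduces the statistical structure every estimator assumes, so the whole
pipeline is testable end to end without field data.

## What it computes

**Molecular diversity partitioning** (`rangegen.popgen`) — Nei's
hierarchical gene-diversity statistics per locus and across loci:

    H_S  = mean_p (1 − Σ_a p_a²)          within-population gene diversity
    H_T  = 1 − Σ_a p̄_a²                   total gene diversity (p̄ unweighted)
    D_ST = H_T − H_S                       among-population differentiation
    F_ST = D_ST / H_T                      proportional differentiation
    F_IS = 1 − H_O / H_S                   inbreeding coefficient

with null alleles treated as a scorable allele class, a missing-data filter
(individuals failing at > 4 loci are dropped), and a rarefy-then-bootstrap
scheme for confidence intervals: each replicate subsamples every population
to a common depth without replacement, then resamples with replacement, and
recomputes all statistics.

**Quantitative-genetic structure** (`rangegen.quantgen`) — a composite
phenotype (the mean of the first three principal-component scores of the
standardized trait matrix, weighted by the % variance of each axis) fed
into the nested random-effects model `y = μ + P_i + F_ij + e_ijk`, fit by
constrained REML (nested-ANOVA method of moments as cross-check), yielding

    Q_ST = V_POP / (V_POP + V_FAM)         selfing-appropriate form
    H²   = V_FAM / (V_POP + V_FAM + V_ERR) broad-sense, total-variance denominator

with parametric-bootstrap CIs on all components.

**Growth-rate plasticity** (`rangegen.plasticity`) — relative growth rates
`GR = Δ ln(size)/Δdays` for stem elongation and leaf area in winter
(days 21→28) and spring (days 55→63) conditions; a family's plasticity
breeding value is the sib-mean of |GR_winter − GR_spring|; species are
compared with a plasticity ~ species + (1 | population) mixed model.

**Population graphs** (`rangegen.popgraph`) — nodes are populations; an
edge survives only where the partial correlation of population allele-dosage
centroids, given all other populations, has an edge-exclusion deviance
`−n ln(1 − r²)` above the χ²₁ critical value at α = 0.05. Community
structure is summarized by the maximum Newman–Girvan modularity over the
edge-betweenness divisive dendrogram.

**Cross-species synthesis** (`rangegen.comparative`) — occupancy-grid range
size (distinct 0.1° × 0.1° cells × 123 km²), F_ST/Q_ST ratios with a
paired-replicate bootstrap and a drift verdict (ratio ≈ 1 under drift),
spatially explicit subsampling of widespread species into compact
5–7-population groups, and OLS regressions of species means on log₁₀ range
size with median r²/P over subsample draws.

## Worked example

```python
import rangegen as rg

cfg = rg.SimConfig(seed=11)                      # 10 pops x 8 families x 4 sibs
gt  = rg.filter_individuals(rg.simulate_genotypes(cfg))
st  = rg.basic_stats(gt)
boots = rg.rarefy_bootstrap(gt, n_boot=1000, seed=11)

pt   = rg.simulate_phenotypes(cfg, structure=(gt.populations, gt.families))
comp = rg.composite_phenotype(rg.derive_traits(pt))
fit  = rg.variance_components(comp.scores.to_numpy(), gt.populations, gt.families)
vcb  = rg.parametric_bootstrap_vc(fit, gt.populations, gt.families,
                                  n_boot=1000, seed=11)
ratio = rg.fst_qst_ratio(boots["F_ST"], vcb["Q_ST"], seed=11)
```

prints, via the obvious accessors:

```
H_O 0.051  H_S 0.480  H_T 0.578  D_ST 0.099  F_ST 0.171  F_IS 0.894
H_S 95% CI [0.483, 0.505]   (rarefaction depth 32)
V_POP 0.238  V_FAM 0.733  V_ERR 0.154  ->  Q_ST 0.245  H² 0.652
Q_ST 95% CI [0.000, 0.467]
F_ST/Q_ST = 0.70, 95% CI [0.41, 6.21], drift not rejected (26 replicates dropped)
```

Read: the simulated species is highly inbred (F_IS ≈ 0.89, as expected at
selfing rate 0.95), moderately structured at markers (F_ST 0.17) and traits
(Q_ST 0.24), and its F_ST/Q_ST interval straddles 1 — indistinguishable
from drift, exactly how the generator constructed it. Note the H_S interval
sits slightly *above* the plug-in point estimate: the interval is a basic
(reverse-percentile) bootstrap interval, which corrects the small-sample
downward bias of plug-in diversity estimators.

A command-line interface mirrors the library
(`rangegen simulate | diversity | qst | plasticity | graph | range |
compare`, with global `--seed`, `--n-boot`, `--alpha`, `--config`, `--out`);
every run writes a JSON summary and a log of seeds and decisions.

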