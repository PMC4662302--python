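# Methods

This note documents the statistical models behind `rangegen`, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices made where more than one defensible option existed.

## Diversity statistics

All gene-diversity statistics are Nei's hierarchical decomposition computed
from allele frequencies. Two estimator families are exposed:

* `plain` (default for testing): plug-in estimators. Their defining
  identities — `D_ST = H_T − H_S`, `F_ST·H_T = D_ST`,
  `F_IS = 1 − H_O/H_S` — hold *exactly*, per locus and across loci, which
  makes them the right basis for invariant tests. They carry the usual
  O(1/n) downward bias: `E[Ĥ_S] ≈ H_S (1 − (1+F_IS)/2n)`.
* `sample_corrected`: Nei–Chesser corrections with harmonic-mean sample
  sizes (formulas in the `basic_stats` docstring), approximately unbiased
  but without the exact identities.

Conventions: `H_T` uses the unweighted mean of population frequency
vectors; across-loci summaries average the H components over loci and
re-derive the ratios from those averages (so the identities survive
aggregation); monomorphic loci have all diversities exactly 0 and their
ratios undefined (excluded from summaries rather than imputed);
`F_IS` is reported clamped to [−1, 1] with the raw value retained. Null
alleles are one extra codominant allele class and null/null homozygotes
count as homozygous; how null homozygotes are distinguished from failed
amplification is a scoring decision upstream of this package — here the
two have distinct codes by construction.

## Rarefy-then-bootstrap intervals

Each replicate (i) rarefies every population to a common depth without
replacement — default depth is the smallest population size, which
equalizes information across populations, the evident purpose of
rarefying — and (ii) resamples with replacement at that depth, then
recomputes all statistics. Both stages can be disabled independently for
diagnostics, and every run logs depth and seed.

The default interval is the **basic (reverse-percentile) bootstrap**
`[2θ̂ − q_{1−α/2}, 2θ̂ − q_{α/2}]`, not the percentile interval. The reason
is quantitative: for plug-in diversity estimators at realistic sample
sizes (n = 20, selfing ≈ 0.95) the bias term `H(1+F_IS)/2n ≈ 0.025` is
about three times the interval width, so a percentile interval essentially
never covers the generating value. The resampling reproduces the same bias
mechanism, and the basic interval — whose validity requires exactly that —
restores near-nominal coverage (measured at ~94–97% for a nominal 95%
interval; see `scripts/acceptance.py`). Percentile intervals remain
available via `ci_method="percentile"`. A consequence worth knowing: the
basic interval need not contain the (biased) point estimate.

Between-group significance throughout the package is the CI non-overlap
rule: two groups differ only if their intervals are disjoint; a shared
endpoint counts as overlap. No multiple-testing correction is applied by
default (a deliberate mirror of how such comparisons are usually reported);
callers can Bonferroni-adjust `level` themselves.

## Composite phenotype and variance components

Traits are centered and scaled to unit variance before PCA, i.e. the
decomposition is of the correlation structure. Traits mix incommensurable
units (mm, mm², counts), so correlation-matrix PCA is the defensible
default; covariance-matrix PCA is available (`scale=False`). Rows with any
missing trait are dropped (complete-case) rather than imputed. Axis signs
are fixed (non-negative loading sums) so scores are reproducible. The
composite is `Σ_k w_k PC_k / Σ_k w_k` with `w_k` the percent variance of
axis k — a weighted mean conventionally divides by the weight sum. Each
species is analyzed separately; pooling across species is the caller's
choice of input.

The nested model `y = μ + P_i + F_ij + e_ijk` is fit by REML under
non-negativity constraints. The restricted likelihood is evaluated exactly
in O(#families) per evaluation by reducing each population block with two
Woodbury steps (family-level compound symmetry, then the rank-one
population term); optimization is Nelder–Mead multi-started from the
ANOVA estimates, an equal-split point, and a residual-only point, with
tight tolerances so that on balanced designs with interior solutions REML
reproduces the closed-form nested-ANOVA estimator to ≤ 1e−6 (a standing
test). The unbalanced nested-ANOVA method of moments (standard
expected-mean-square coefficients, negative solutions truncated at zero)
serves as the cross-check estimator and as a fast refitter for bootstrap
work. An independent mixed-model implementation (statsmodels `MixedLM`) is
used in the test suite as an external oracle, never in the pipeline.

Definitions follow the selfing-appropriate convention: families are
(nearly) selfed sib groups, so among-family variance approximates the
total genetic variance within populations and `Q_ST = V_POP/(V_POP+V_FAM)`
without the factor 2 used for outcrossed half-sib designs. Broad-sense
heritability uses the *total* variance denominator,
`H² = V_FAM/(V_POP+V_FAM+V_ERR)` — note this is not the common
within-population definition, and the two differ whenever `V_POP > 0`.

Uncertainty comes from a parametric bootstrap on the original design
(simulate normal effects from the fitted components, refit, collect all
six quantities), with percentile intervals: REML variance components are
close to unbiased at these designs, so the percentile/basic distinction
that matters for plug-in diversity statistics does not arise here.

## Plasticity

Growth rate is the log-difference rate per day, applied to height (stem
elongation) and leaf area; the winter rate spans days 21→28 and the spring
rate days 55→63, the measurement pairs that bracket the vernalization and
spring chamber phases. The printed source formula for stem elongation
contains an obvious duplicated-t2 typo; the intended log-difference form is
used. Plasticity is |ΔGR| per individual first, then averaged over sibs to
give the family breeding value (the alternative — differencing family-mean
growth rates — is available by computing on family-aggregated records).
Because leaf-area and stem-elongation rates live on different scales, the
combined "mean plasticity" z-standardizes each trait's family values within
the analysis set before averaging (`standardize=False` gives the raw mean).

The species comparison is `plast ~ species (fixed) + population (random)`,
fit by a profiled REML specialized to this design (populations nested in
species make the GLS species means inverse-variance-weighted population
means; the single variance ratio is optimized in 1-D). Fixed-effect
uncertainty is parametric-bootstrap; significance is CI non-overlap.

## Population graphs

Individuals are encoded as allele-dosage vectors (one coordinate per
allele class, value ∈ {0, ½, 1}); one reference class per locus is dropped
because within-locus frequencies sum to one and would otherwise make the
centroid matrix exactly collinear. The among-population covariance of
centroid vectors (coordinates as observations) is standardized to a
correlation matrix; its inverse gives partial correlations, and the
edge-exclusion deviance `−n ln(1 − r²)` with n = total individuals (the
sample actually supporting the covariance; the population count is the
documented alternative) is tested against χ²₁. Near-singular matrices fall
back to a ridge-regularized pseudo-inverse (1e−8, logged); exactly
duplicated centroids raise an error naming the pair.

Edge weights are the conditional distance `sqrt(1 − r²)`; several
conditional-distance weightings exist in the literature, and the choice is
immaterial here because community detection runs on the **unweighted**
retained topology: edge-betweenness divisive clustering with betweenness
recomputed after each removal, scored by Newman–Girvan modularity at every
dendrogram level plus the single-community and connected-components
partitions (the latter matters for disconnected graphs, where the first
divisive split can jump past the best partition). An edgeless graph has
modularity 0 by convention.

## Range size, ratios, subsampling

Range size is the count of occupied 0.1° × 0.1° cells times a constant
123 km² regardless of latitude — the convention this pipeline reproduces —
with a latitude-corrected variant behind a flag. Cells are half-open,
lower-left inclusive, with a 1e−9-degree rounding guard so points on cell
edges are binned consistently.

The F_ST/Q_ST point ratio divides point estimates; its uncertainty pairs
replicate r of the two bootstrap distributions (independent resampling
when lengths differ), dropping and counting replicates with Q_ST < 1e−6.
Both drift rules are provided: CI excludes 1 (default) and mean ± SD
excludes 1. When the diagnostic is averaged over replicate *species* (the
neutrality experiment), the summary is the ratio of mean F_ST to mean
Q_ST. The per-replicate mean of ratios is not used deliberately: with ~9
populations of freedom, Q̂_ST has continuous probability mass near zero,
so the expectation of 1/Q̂_ST — and with it the mean of per-replicate
ratios — diverges; the ratio of means is the stable summary and matches
how a single species' ratio is formed from its bootstrap means.

Spatial subsampling grows each group from a random seed population by
accreting great-circle nearest neighbours to a uniform-random size in
[5, 7] (a reproducible stand-in for hand-drawn sampling polygons with the
same size and extent constraints); group extent is the convex-hull area
after local equirectangular projection, and an extent window can reject
and redraw groups. Hull areas are floored at one grid cell (123 km²)
before log-transformation in regressions, so collinear groups remain
usable. Regressions are OLS of species means on log₁₀ area; with four
species they have very low power, which the result object logs — r² is
the primary summary, the median r² and P over draws are reported for
subsample analyses. A constant response is reported as slope 0, r² 0.

## Synthetic-data generator

Genotypes follow the Balding–Nichols island model (flat-Dirichlet
ancestral frequencies; population frequencies Dirichlet-scattered with
parameter `(1−F)/F`), chosen because it gives an analytic F_ST target and
therefore exact expectations for estimator-recovery tests. Selfing is
modeled at inbreeding equilibrium (`F_IS = s/(2−s)`, alleles within an
individual identical with that probability) rather than by forward
simulation — the mating system matters here for statistical structure,
not dynamics — and sibs are drawn iid from their population's equilibrium
distribution (selfed sib groups share the maternal distribution, not a
literal maternal genotype). Null alleles are injected by relabelling one
allele class at a fraction of loci, which leaves every diversity statistic
invariant by construction; missing genotypes are MCAR.

Phenotypes: three latent factors, each an independent nested normal with
variances (v_pop, v_fam, v_err); observed log-sizes are fixed linear
combinations of the unit-scaled factors plus trait-specific noise,
exponentiated so sizes are positive and log-growth arithmetic is exact.
Because all factors share the same variance ratios, *any* linear composite
of the traits has among-population fraction `v_pop/(v_pop+v_fam)` — the
property the Q_ST tests rely on; trait-specific noise dilutes only H².
Six measured traits are generated (heights, leaf areas, leaf counts at
days 21 and 55); the two ratio traits of the eight-trait analysis set
(internode distance, leaf size) are definitional ratios and are derived
downstream exactly as in the analysis, not simulated independently. The
trait loading matrix is a free parameter (no empirical trait-correlation
targets exist for these species); the default gives three dominant PCA
axes. Growth: family-by-environment rates `GR = env_mean + d/2` with a
family plasticity contrast `d ~ N(0, plasticity_sd²)` split between
environments; `SD(|GR_w − GR_s|) ≈ plasticity_sd` holds because the
environment contrast (0.06/day by default) dominates the contrast SD.

Defaults are the study conditions: 10 populations × 8 selfed families ×
4 sibs, 15 loci of 5 allele classes, F_ST target 0.2, selfing 0.95, nulls
at 20% of loci, 2% missing, trait variances (v_pop, v_fam, v_err) =
(1, 4, 1) — i.e. trait Q_ST 0.2 matched to the marker target, and
H² = 2/3, typical of selfed families scored in a controlled chamber, with
genetic variance dominating the residual so that variance-ratio estimates
are well-conditioned. Winter/spring mean growth rates are 0.02 and 0.08
per day with a 0.02/day plasticity SD.

What the generator does **not** emulate: stepwise-mutation allele-size
structure, linkage, isolation by distance (populations are exchangeable
islands), genotyping artefacts beyond MCAR missingness and null classes,
apomixis/ploidy variation, selection on any trait, and G×E beyond the
family-level growth-rate contrast. Passing tests therefore validate the
estimators under their own assumptions — exchangeable island structure
and normal nested trait effects — not robustness to these violations.

## Experiment sizes

The calibration experiments are sized to be decisive yet desk-scale: the
neutrality experiment uses 100 replicate species at the default design;
the coverage experiment 200 datasets × 200 bootstrap replicates (quantile
noise at 200 replicates is well inside the 90–99% acceptance band);
parameter-recovery runs use 200 replicates at a 30 × 10 × 4 design, where
the standard error of the mean estimate is ~1.5% of the target. Fuzzing
against brute-force oracles uses 1000 random tables (diversity) and 100
random ≤ 7-node graphs (exhaustive modularity, Bell(7) = 877 partitions).

## Known limitations

* The rarefaction depth of the original bootstrap procedure is not
  recoverable; `depth="auto"` (smallest population) is a choice, and both
  resampling stages are switchable so alternatives can be composed.
* `internode distance = leaf number / height` is implemented as printed
  even though the name suggests its reciprocal; `invert_internode=True`
  gives the dimensionally conventional form.
* P values from 4-species regressions are reported but nearly powerless;
  the median-over-draws machinery treats r² as primary.
* REML fits with boundary solutions (any component at 0) make ratio
  statistics (Q_ST, F_ST/Q_ST) heavy-tailed; the dropping rules and
  ratio-of-means summaries above are the mitigations, and dropped counts
  are always reported.
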