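# Methods

## The comparative design and its inferential problems

The design pairs each domesticated species with a wild counterpart
("dyad") and asks whether domestication shifts gut community composition
in a consistent direction. Three features of the data drive every
methodological choice here:

1. **Host lineage dominates.** Between-dyad differences explain far more
   compositional variation than domestication status, so status must be
   tested *within* dyads: the status factor is nested in the dyad factor,
   and status labels are exchangeable only among samples of the same dyad.
2. **Ordination axes are only identified up to rotation and sign.** Any
   directional claim ("domesticates shift rightward") is meaningless until
   a sign convention is fixed.
3. **Pairwise dissimilarities are not independent.** Two dissimilarities
   that share a sample share an individual's community; treating the
   n(n−1)/2 pairs as independent observations inflates test statistics.

## Pipeline procedures

**Dissimilarities.** Bray–Curtis is computed on relative abundances
(1 − 2Σmin(pᵢ,qᵢ)/(Σp + Σq)). With sequencing depths spanning close to an
order of magnitude (the depth model below), raw-count Bray–Curtis makes
the leading ordination axis track library size almost perfectly
(r ≈ 0.99 with log depth on synthetic data), so proportion-based
computation is the default; a `normalize=False` flag retains the raw form.
UniFrac (unweighted: unshared branch length over union branch length;
weighted: Σ_b ℓ_b |p_A(b) − p_B(b)|, normalized by Σ_b ℓ_b (p_A + p_B))
goes through scikit-bio and is verified against a brute-force edge
enumeration. Alpha diversity (Shannon, base 2 by default, matching the
QIIME-era convention; observed richness) is computed on tables rarefied to
a fixed depth by a single seeded multivariate-hypergeometric draw per
sample — retained totals are exact, under-depth samples are dropped and
logged.

**Ordination.** NMDS minimises Kruskal stress-1
√(Σ(d − d̂)²/Σd²), where d are configuration distances and d̂ their
isotonic regression on the observed dissimilarities (weak/primary tie
treatment: ties are averaged by the pool-adjacent-violators algorithm;
tie handling shifts stress in the third decimal, so it is fixed and
documented rather than configurable). Optimisation is SMACOF with one
start from the PCoA configuration plus random restarts (default 20,
max 300 iterations, tolerance 1e-7 — mirroring the defaults of the R
tool this workflow is usually run with); the PCoA start itself remains a
candidate, so the returned stress never exceeds the start's. The final
configuration is rotated to principal axes, making axis 1 the
max-variance direction. PCoA is the eigendecomposition of the
Gower-centered squared-dissimilarity matrix; negative eigenvalues
(non-Euclidean input) are reported signed and their axes excluded.

**Orientation.** The `anchor_group_positive` rule flips axis 1 so that
mean(domesticated) − mean(wild) ≥ 0, and higher axes so their
largest-magnitude coordinate is positive. Applied before any shift
statistic; sign flips only, so no distance changes. All directional
results in the package are defined relative to this rule.

**Ordination shift.** A sample's displacement is its axis-1 coordinate
minus the mean axis-1 coordinate of its dyad (all dyad members included;
displacements therefore sum to zero within each dyad), or minus the
all-primate mean for the human/chimp cohorts. Wild and domesticated
displacement distributions are compared by Mann–Whitney U, overall, per
dyad, and per domestication category with Bonferroni across categories.

**Nested PERMANOVA.** Sequential (Type I) partitioning of
SS_total = Σᵢ<ⱼ d²ᵢⱼ/n via the Gower-centered matrix G: term j contributes
SS_j = tr((H_j − H_{j−1})G) with H_j the hat matrix of the cumulative
dummy-coded design; pseudo-F_j = (SS_j/df_j)/(SS_res/df_res) and
R²_j = SS_j/SS_total (residual R² reported so ΣR² = 1). Significance by
permuting samples — freely, or within dyad strata for the nested status
term (the standard restricted-permutation reading of "status nested within
species pair"). Permutations tying the observed F (e.g. relabelings that
preserve the grouping) count as exceedances; consequently the attainable
minimum p for a 5+5 two-group design is ≈ 1/126, not 1/(B+1).

**Dispersion.** Per-sample distance to its group centroid in the
positive-eigenvalue PCoA embedding; one-way F across groups; p by
permutation. When group labels are permuted, centroids are *re-estimated
under the permuted grouping* — permuting fixed distances-to-centroid
leaves centroid-estimation noise out of the null and inflates the type-I
rate to ≈ 0.06 in simulation. For the wild-vs-domesticated contrast the
centroids are the host-species centroids (a fixed nuisance structure) and
only the status labels are permuted. Centroids, not spatial medians, for
analytic simplicity; no bias-adjusted variant.

**Stratified bootstrap for pairwise dissimilarities.** The resampling
unit is the individual: within each stratum (by default the set of
comparison groups an individual's pairs span; explicitly specifiable),
n−1 of the n individuals are drawn with replacement — the classic cluster
bootstrap correction for the (n−1)/n variance shrinkage of the naive
n-of-n draw. Each replicate induces a pair multiset (pair multiplicity =
product of its endpoints' draw counts) on which the Mann–Whitney U is
recomputed; the two-sided p is twice the smaller tail fraction of
replicates whose centered statistic U − n₁n₂/2 falls on either side of
zero, floored at 1/(B+1), with a percentile interval of the centered U
reported alongside. In strata whose individuals each appear in exactly one
pair the dependence graph is empty and the unit degenerates to the pair:
such strata are bootstrapped at the pair level directly (product
multiplicities would inflate replicate variance roughly threefold and make
the test severely conservative). The Kruskal–Wallis variant reuses the
same resampling and reports a crossing-based p (fraction of replicates
whose H falls at or below the χ²_{k−1} median, floored at 1/(B+1)) — a
heuristic omnibus analogue, flagged as such. 25,000 resamples is the
reference setting; the analysis drivers default to 2,000, which puts the
p floor at 1/2001 — far below every decision threshold used here.
This individual-level scheme is the package's main interpretive decision:
the procedure it operationalises is a resampling correction for the
non-independence of dissimilarities sharing individuals, and the
calibration and dependence-discrimination batteries in the test suite are
its specification.

**Mixed-model likelihood tests.** Response = axis-1 coordinate; full and
null fixed-effect sets differ by the term of interest (treatment group in
experiments; status in the divergence analysis, with log₁₀ divergence time
as a fixed covariate); a single random intercept (individual, or dyad).
Both models are fit by maximum likelihood (not REML — fixed effects
differ), LRT referred to χ² with df = parameter difference. The optimiser
falls back across lbfgs/bfgs/powell/nm because boundary fits (zero
random-effect variance) occasionally break the default.

**Rank tests.** Mann–Whitney, one-sample Wilcoxon, Kruskal–Wallis and
Spearman wrap scipy.stats with exact small-sample paths (MWU: exact for
n₁+n₂ ≤ 12 without ties; Wilcoxon: n ≤ 15; KW: optional full enumeration
of value-to-group assignments). Bonferroni (min(1, m·p)) is applied within
each reported family of comparisons. All tests default two-sided.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
any real taxon content.

*Latent model.* Host lineages evolve on a random coalescent (root at
8×10⁷ years) by Brownian motion, scaled so dyad centers have spread
σ_dyad = 5 along latent axis 1 and 0.35·σ_dyad on other axes — recently
diverged hosts are compositionally close, giving the Mantel divergence
analysis genuine signal, and axis 1 is the dominant-variance direction the
planted shift acts along. Within a dyad, species centers sit at
± (δ + coupling·divergence)/2 along axis 1 (δ = 2.0 by default), with the
domesticated species on the positive side; samples scatter around their
species center with status-specific spread (σ_dom = 1.0, σ_wild = 2.0 —
wild communities are more dispersed). Samples map to compositions by a
log-linear model: composition = softmax(b + Lz) with loadings
L ~ N(0, 0.35²) and intercepts b ~ N(0,1).

*Counts.* Reads are Dirichlet-multinomial: p ~ Dirichlet(θ·composition)
with θ = 600, then multinomial at a lognormal depth with mean 158,611 and
sd 109,567 reads — the observed depth regime of survey-scale 16S data.
θ and the loading scale were set once so that within-species Bray–Curtis
dissimilarity sits at ≈ 0.45–0.50, the regime typical of mammalian gut
communities; the pure replicate-noise floor at θ = 600 is ≈ 0.24.

*Pathogens.* A subset of taxa (15/150) represents potential pathogens:
rare (intercepts shifted by −5 log-units) and enriched log(4)-fold in wild
samples. Rarity is what makes rarefied pathogen *richness* a detection
contrast, not just abundance.

*Primate cohorts.* Chimpanzees, five non-industrialized and two
industrialized human populations (7 samples each). The cohort center is
anchored at +0.5·σ_dyad on axis 1 — so the industrialized populations,
shifted a further δ rightward, occupy the domesticated edge of the joint
space, the configuration the comparative claim is about — and the
Pan–Homo divergence is fixed at 6.5×10⁶ years in the host table.

*Longitudinal experiments.* Individuals start at their species center plus
an individual intercept (σ = 0.4) and drift linearly toward the target
(the other species' center under a reciprocal diet; the donor community
after colonization, as an instantaneous jump). The drift asymmetry of the
reciprocal-diet design (wild-host recipients converge 0.8 of the way,
domesticated-host recipients 0.3) is planted deliberately. The single
experimental dyad sits at the latent origin: a large random offset pushes
the softmax into a saturated corner where the leading ordination axis
decouples from the planted dynamics.

*What the generator does not emulate:* real taxon identities or
phylogenetic signal in abundances (the taxon tree is independent of the
loadings by default), compositional covariance beyond the low-rank latent
structure, contamination or batch structure, and alpha diversity is not
controlled — the wide wild spread slightly lowers wild evenness as a side
effect, so status contrasts of Shannon/richness on synthetic data reflect
that artifact rather than a planted effect. Passing tests therefore
demonstrate correctness and calibration of the *procedures* under the
assumed dependence structure, not recovery of any real biological values.

## Numerical choices and degenerate inputs

- Seeded `numpy.random.Generator` everywhere; every stochastic result
  carries its seed. Permutation p-values are (1 + #{exceedances})/(B + 1)
  and never fall below 1/(B+1); ties count as exceedances with an
  8-decimal float tolerance.
- Rank tests on all-identical inputs return p = 1 with a degeneracy flag
  instead of propagating NaNs; zero-sum samples are rejected before any
  dissimilarity; dyads with a single status are excluded (with a warning)
  from shift analyses; individuals missing the day-0 sample are excluded
  from displacement statistics.
- NMDS stress comparisons across implementations are only meaningful at
  matched tie treatment; this package's stress-1 is computed by one shared
  routine for candidates, starts and reported values.

## Problem sizes used in validation

The test suite runs oracle checks on 50 randomized 8-taxon instances;
exhaustive enumeration up to 6 labels (PERMANOVA, Mantel) and n ≤ 9 rank
configurations; calibration batteries of 400 replicates per procedure at
small per-replicate designs (12–30 samples, 99 permutations, 499
bootstrap resamples) with the 95% binomial interval around α = 0.05; and
power batteries of 100 replicates at the survey-scale design (9 dyads,
5–20 samples per species) with 2 NMDS restarts per replicate. The
acceptance script runs the full pipeline at 999 permutations, 2,000
bootstrap resamples and 4 NMDS restarts. These sizes are the package's
validation settings; all defaults in `RunConfig` remain at the reference
analysis values (999 permutations, 25,000 resamples, 20 restarts).

## Known limitations

- The stratified bootstrap is approximate for very few individuals per
  stratum (< ~10): simulated type-I error rises toward ≈ 0.07 at 12
  individuals per class. The LRT for mixed models shares the usual
  small-sample χ² anticonservativeness.
- The bootstrap Kruskal–Wallis p is a heuristic; for two groups the MWU
  form is the calibrated procedure.
- Sequential PERMANOVA R² depends on term order by construction; the
  pipeline fixes dyad → status and reports the residual so the partition
  is explicit.
- The Mantel divergence test inherits whatever structure the divergence
  matrix has; with only within-dyad times and a constant deep split it is
  underpowered (the host-divergence matrix input exists for exactly this
  reason).
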