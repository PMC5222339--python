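# Methods

This note records the statistical models implemented in `clonestruct`,
the estimator conventions chosen where several exist, the design of the
synthetic-data generator, and the numerical and degenerate-input policies.

## Clone discrimination

Two complete multi-locus genotypes belong to the same MLG iff every locus
carries the identical unordered allele pair.  Samples with any missing
call are excluded from discrimination (`complete_cases`) because identity
is undecidable there; triploid or ambiguous peak profiles are expected to
have been normalized to missing upstream.  MLG ids are assigned by
decreasing abundance (ties by first occurrence), so `MLG01` is always the
dominant clone.

**P_gen / P_SEX.**  The probability of drawing a given genotype in one
sexual event under inbreeding coefficient F_IS multiplies per-locus terms
2·f_A·f_B·(1−F) (heterozygote) and f_A² + f_A(1−f_A)·F (homozygote).
P_SEX for an MLG observed n times among N units is the binomial upper
tail over the other N−1 units: P(X ≥ n−1), X ~ Binomial(N−1, P_gen) —
the "N−1 other units" convention; the all-N variant differs negligibly
and is not offered.  Allele frequencies feeding P_gen and P_ID default to
the genet-level scheme (one representative per MLG per population) to
avoid clonal inflation; ramet-level counting is available by flag.  The
F_IS plugged into P_gen is a single multilocus population estimate, by
default from the truncated dataset.

**SMM distance.**  Per locus the two possible pairings of the diploid
allele pairs are evaluated and the cheaper one kept, in units of the
locus's repeat motif; loci whose allele sizes are not congruent modulo
the motif raise an error naming the locus.  The per-locus minimum pairing
can violate the triangle inequality; only symmetry and the zero diagonal
are guaranteed, and nothing downstream assumes metricity.

**MLL threshold.**  The collapse threshold is read off the first empty
integer bin of the inter-MLG distance spectrum: genuinely distinct genets
differ by many steps, so somatic mutation and scoring error occupy a
leading band separated by a gap.  When the minimum observed distance is 1
there is no leading gap and the threshold is 0 — no collapsing is
defensible from the spectrum alone.  Note the interaction with the
generator: a single somatic step creates an MLG at distance 1 from its
source, which by this rule suppresses automatic collapsing; the
truth-recovery test therefore collapses at the maximum intra-genet
divergence taken from the simulation truth, which restores the genet
count exactly.  Collapsing is single-linkage (connected components of
the ≤-threshold graph); each MLL is labelled by its most abundant member.

## Diversity indices

R = (N_MLG−1)/(N−1).  G_O = 1/Σp_i² (inverse Simpson concentration of
clone sizes) and G = G_O/N, which spans (0,1] — 1 when every colony is a
distinct genet.  ED* rescales the unbiased Simpson index
D = 1 − Σn_i(n_i−1)/(N(N−1)) between the least-even configuration with
the same N and G (one clone of N−G+1 plus singletons) and the most even
one (sizes differing by ≤1); it is undefined (reported as None in
reports, an error in direct calls) for monoclonal or all-singleton
populations.  The Pareto exponent is −slope of the OLS fit of
log(fraction of clones of size ≥ x) on log x over the distinct observed
sizes, one support point per size.  Rarefied allelic richness uses exact
hypergeometric rarefaction, Σ_a [1 − C(2n−n_a, g)/C(2n, g)] per locus
averaged over loci, computed in log-gamma space; the default rarefaction
size is twice the smallest per-population genet count.  H_E is unbiased
Nei diversity (2n/(2n−1))(1 − Σp²); heterozygosities are computed on the
genet-level table.

## Spatial statistics

All three statistics use site-local planar coordinates in meters; sites
without coordinates are skipped, not erroed.  Significance uses the
(b+1)/(m+1) permutation estimator with a recorded seed (default 10³
permutations), so p-values are bit-reproducible.

* **Ac** = (P_nn − P_all)/(1 − P_all), where P_all is the clonemate
  fraction among all pairs and P_nn the fraction of colonies whose
  nearest neighbour (Euclidean, ties to the lowest index) is a clonemate;
  0 in expectation under random labelling, 1 under complete aggregation.
  One-sided test, MLG labels shuffled over fixed coordinates.
* **Ee** = (D_uniq − D_all)/D_all, mean distance to the sample centroid
  of singleton-MLG colonies relative to all colonies; positive values
  put fresh genotypes at the periphery.  One-sided (greater) test.
* **Moran's I** is computed per (locus, allele) on allele dosages
  x_i ∈ {0, ½, 1} with inverse-distance weights collapsed to a single
  distance class (coincident pairs receive the minimum positive
  distance), then averaged over alleles weighted by allele variance;
  zero-variance alleles are skipped.  Two-sided test by permuting the
  coordinate assignment; the permutation-null mean is −1/(n−1).

These normalizations satisfy the qualitative contracts (null
expectation 0 for Ac/Ee, 1 under full aggregation, sign = edge vs
center) and are artifact-defined; legacy clonality software does not
publish its exact formulas.

## F-statistics and differentiation

F_IS and F_ST are the Weir–Cockerham (1984) variance-component
estimators, aggregated as ratio-of-sums over alleles and loci (the
standard multilocus form).  The F_IS null shuffles the observed allele
copies among individuals within the population at each locus and reports
the doubled smaller tail.  Pairwise θ p-values permute whole multilocus
individuals between the two populations (one-sided, θ_perm ≥ θ_obs).
Jost's D_est uses Ĥ_S = (2ñ/(2ñ−1))(1 − mean_i Σ_a p²_ia) with ñ the
harmonic mean sample size, Ĥ_T = 1 − Σ_a p̄²_a from unweighted mean
frequencies, D = (Ĥ_T − Ĥ_S)/(1 − Ĥ_S)·r/(r−1); the multilocus value is
the arithmetic mean over loci polymorphic in the pair (the
harmonic-mean-of-1/D variant is not implemented).  Genotypic
disequilibrium between locus pairs uses the likelihood-ratio G statistic
of the single-locus-genotype contingency table with one locus's column
permuted; Bonferroni correction divides α by the number of tested pairs.

Every differentiation statistic is computed twice: on the entire dataset
(clonal replication weights genotypes by ecological success) and on the
truncated one (one representative per MLG per population, all genets
equal).  Loci flagged `excluded` in the panel — the configuration hook
for null-allele loci — are removed from both structure analyses but kept
for clone discrimination and diversity.  Per-stage failures (e.g. a
monoclonal population truncating below the estimator's minimum) are
collected into the report instead of aborting the run.

## Ordination and network

The "PCA on a Dice dissimilarity" tradition is implemented as principal
coordinates: Gower double-centering of −d²/2, symmetric
eigendecomposition, coordinates scaled by √λ.  Negative eigenvalues
(possible for non-Euclidean inputs) are reported but excluded from the
variance percentages and carry no coordinates.  The clone network joins
MLG pairs whose shared-allele distance D_AS = 1 − (shared copies)/(2L)
falls below a threshold; when no threshold is given, the percolation
threshold — the smallest edge weight making the graph connected, found by
binary search over the sorted unique weights — is used, giving the
sparsest fully connected view.

## Synthetic-data generator

The generator emulates a four-site survey of a partially clonal coral:

| parameter | default | meaning |
|---|---|---|
| site_sizes | (158, 264, 42, 46) | colonies per site |
| n_loci / alleles_per_locus | 13 / 6 | microsatellite panel; motifs cycle 2,3,4 bp on a ladder from 100 bp |
| divergence_f | 0.2 | Balding–Nichols divergence of the two clusters around Dirichlet-uniform ancestral frequencies |
| cluster_of_site | north, north, mixed, south | the mixed site draws genets 50:50 from both clusters |
| f_is | 0.15 | probability a locus is made identical-by-descent in a founder draw |
| superclone_fraction | 0.47 | share of all ramets held by the largest clone |
| pareto_beta | 1.5 | discrete-Pareto exponent of the remaining clone sizes |
| site_radius / ramet_dispersal_sigma | 12 m / 1.5 m | sampling disc; Gaussian scatter of ramets around their genet's origin, reflected into the disc |
| clonal_migration_rate | 0.01 | per-ramet probability of reassignment to another site with a fresh origin |
| somatic_mu | 0.0005 | per-locus per-ramet probability of a ±1-motif stepwise mutation |
| missing_rate | 0.01 | per-locus per-ramet missing-call probability |

Defaults were chosen once to match the emulated survey's reported scale:
the site sizes, 12 m discs, 47% superclone and ~0.2 between-cluster
divergence are the survey's own figures; f_is, the Pareto exponent,
dispersal, migration, mutation and missing rates are set to values a
field population geneticist would call realistic for such data (truncated
F_IS estimates of 0.1–0.3, a heavy-tailed clone-size spectrum, meter-
scale fragment reattachment, rare long-distance clonal transport,
somatic mutation and dropout at the per-mille level).

Clones are drawn globally (superclone = round(fraction·N), remainder
discrete Pareto truncated to conserve N exactly), then placed whole into
a single home site drawn proportionally to remaining quota among sites
that can hold them — so the superclone lands in the largest site, and
with migration disabled every MLG is confined to one site.  Cross-site
clonemates arise only through the migration step.  All randomness flows
through one seeded Generator in a documented draw order; a seed
reproduces the dataset bit for bit.

What the generator does **not** emulate: genotyping artefacts other than
uniform dropout (allele dropout correlated with allele size, stutter,
null alleles), selection or fitness differences among genotypes,
overlapping generations and coalescent ancestry, non-isotropic dispersal,
and real lagoon geometry.  Passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to every field
artefact.

## Temperature and phenology

The degree-day module accumulates the daily difference of two aligned
series, extrapolates the observed mean daily difference over the
unobserved remainder of the year, and divides the annual cumulative
difference by the warmer site's mean daily temperature to express it as
whole days of gamete-maturation delay — the only arithmetic consistent
with treating accumulated heat as the maturation requirement.  The
synthetic series is an annual sinusoid plus a constant site offset and
Gaussian noise.

## Validation design and problem sizes

The test suite validates each estimator three ways: closed-form or
hand-enumerated values on tiny instances; independent oracles (exact
rational binomial tails for P_SEX, brute-force enumeration over all 2^13
pairings for the SMM distance, an independently coded Weir–Cockerham
component evaluation, scikit-bio's PCoA); and calibration/recovery on
simulated data.  Type-I-error calibration runs 500 replicates per test at
199 permutations each, with populations of 30 genets (F_IS, Moran), 60
genets (disequilibrium) and 500 spatial units (Ac/Ee).  The spatial
calibration uses 500 units because the nearest-neighbour clonemate count
is integer-valued: at a few hundred units the null distribution's atoms
near the 5% quantile make the test visibly conservative, which is a
resolution artefact of small samples rather than a property of the test.
Parameter recovery averages 20 replicates for θ (13 loci, 50 genets per
population) and 10 replicates for the Pareto exponent, whose single-draw
OLS estimate at 500 clones spreads more widely than the ±0.3 recovery
band.

## Known limitations

* Ac/Ee normalizations are artifact-defined (see above); absolute values
  are not comparable across software, only signs and p-values.
* D_est across loci is the arithmetic mean of per-locus values;
  harmonic-mean pooling would give slightly different multilocus values.
* The MLL gap rule returns 0 whenever distance-1 pairs exist, which is
  conservative in the presence of genuine somatic variation (see Clone
  discrimination).
* The lineage gate is Hamming-based on the shared leading window; it
  assumes a fixed-length amplicon and does not handle indels.
* Per-locus F_IS is reported but the P_gen correction uses a single
  multilocus F_IS value.
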