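# Methods

This note records the models, estimators and numerical choices behind the
package, what the synthetic generators do and do not emulate, and the known
limitations.

## Data model

Accessions of a highly selfing species are treated as haploid multilocus
genotypes: calls are coded 0/1 per biallelic SNP with −1 for missing, and a
sample carries population, subregion/group, region and coordinates.
Locus filtering is applied in a fixed order — missingness (drop loci with a
missing fraction ≥ `max_missing`, default 0.25), then monomorphism within
the analysis scope, then loci unobserved in an entire population — so the
per-filter removal counts are reproducible. Haplotype collapsing offers two
missing-data rules: `strict` (missing is a distinct state; the default) and
`wildcard` (samples merge when they agree wherever both are observed, closed
transitively by union–find). `strict` can only split groups that `wildcard`
joins, so its haplotype count is an upper bound on the wildcard count.

## Diversity

Gene diversity per locus is *h* = 1 − Σ *p*² (`plain`, the default,
matching the common gene-diversity convention for haploid data) with the
small-sample corrected *n*/(*n*−1)·*h* available as `unbiased`. Unit means
are accompanied by the standard error over loci — the ± values shown in the
report tables — not a bootstrap.

Rarefied allelic richness uses the closed-form hypergeometric estimator: an
allele with *N*ₐ of *N* observed copies appears in a random subsample of
size *g* with probability Q = 1 − C(*N*−*N*ₐ, *g*)/C(*N*, *g*); the expected
allele count is the sum of Q over alleles, and private richness multiplies
the focal unit's Q by Π(1 − Q) over the other units. Binomial coefficients
are evaluated through log-gamma for stability. The estimators agree exactly
(≤ 1e−12) with exhaustive subsample enumeration on all instances with
N ≤ 8, which the test suite verifies. The default rarefaction size *g* is
the smallest per-locus observed-call count across the compared units; loci
with fewer than *g* calls in a unit are skipped for that unit.

Nucleotide diversity π is the mean over sequence pairs of
differences/compared-sites, with gaps and ambiguity codes excluded pairwise.
Silent-site classification is caller-supplied; the package does not infer
gene models.

## Differentiation (AMOVA)

The AMOVA distance is the count of differing loci between two haploid
genotypes under pairwise deletion — the squared Euclidean distance for 0/1
calls. Sums of squared distances within/among units give mean squares, and
variance components follow from the standard unbalanced-design coefficients
(n₀ for the one-level design; n′, n″, n‴ for the two-level
group/population/individual design). Fixation indices are ratios of
truncated-at-zero components (the raw, possibly negative components are
retained in the result object with a flag). Significance uses the standard
permutation schemes — individuals among populations for F_ST, whole
populations among groups for F_CT, individuals among populations within
their group for F_SC — with the (b+1)/(n+1) p-value convention so p is
never zero; permutation streams are seeded. Pairwise F_ST is the two-unit
AMOVA, which the tests pin to the full AMOVA as an identity.

Between-group distances report the raw mean cross-group allele difference
and the net (corrected) distance raw − (d̄_A + d̄_B)/2, where the
within-group means run over all ordered pairs (π-style, self-pairs
included): with that convention the net distance of a group against itself
is exactly zero and the value is invariant to duplicating every member of a
group.

## Isolation by distance

Geographic distances are great-circle (haversine) on a sphere of radius
6371.0088 km; the error against an ellipsoid is negligible at the scales
involved. The Mantel statistic is the Pearson correlation of the two
distance matrices over their upper triangles; the null permutes rows and
columns of one matrix jointly; the default alternative is one-sided positive
(the IBD expectation), with the genetic-on-geographic regression slope
reported alongside. The regional IBD comparison takes the combined
distance matrices plus a population→region map and permutes the region
labels, recomputing both regions' r and slope per permutation — a
two-sided test on Δr and Δslope. (Disjoint per-region matrix pairs are not
enough: recomputing statistics under permuted labels needs the cross-region
distances, which is why the function takes combined matrices.)

## Clustering

**PCA route.** Loci are centred by allele frequency and scaled by
√(p(1−p)); missing calls are mean-imputed before scaling; monomorphic loci
are dropped. Optional LD damping residualises each locus on its one or two
preceding loci in map order. Eigenvalues of the sample covariance are
tested sequentially with the Tracy–Widom (β = 1) law after moment-matched
normalisation (effective marker count from the eigenvalue sum and sum of
squares). The TW CDF itself is computed from the Painlevé II
representation — the Hastings–McLeod solution is integrated from s = 8
(Airy initial conditions) down to s = −10 with DOP853 at rtol 1e−12
(looser tolerances fall off the unstable manifold near s ≈ −7), the tail
integrals accumulated alongside, and the result cached as a monotone PCHIP
interpolant; the computed 5%/1%/0.1% points match the published thresholds
(0.9793 / 2.0234 / 3.2724) to ~1e−6. Components explaining ≥ 2% of
variance, clipped to between 3 and 5, are weighted by their eigenvalues and
clustered by Ward linkage; without a fixed k the dendrogram is cut at the
largest relative jump in merge heights.

**Admixture route.** The haploid admixture likelihood
L = Σᵢₗ log Σₖ qᵢₖ·[pₖₗ if xᵢₗ=1 else 1−pₖₗ] is maximised by EM
(block relaxation of Q and P) from seeded Dirichlet/uniform starts; missing
calls are skipped; cluster frequencies are clipped to [1e−6, 1−1e−6]. The
iteration is provably monotone (asserted at run time) and stops at relative
tolerance 1e−5 or 300 iterations (flagged, not raised). A "run" keeps the
best of `n_starts` (default 3) random starts, absorbing local-optimum
variability. K = 1 has the closed-form solution.

**Choosing K.** The selection rule is a ladder of two-sided Wilcoxon tests
(α = 0.005, replicates paired by index; a rank-sum variant is available)
on per-run statistics, with K the largest value whose step and all smaller
steps are significant with positive median improvement. The statistic fed
to the ladder matters: the *maximised* likelihood is monotone in K on any
data (each added cluster brings n + L free parameters), so it cannot drive
this rule. Instead each run is scored by the exact Bayesian evidence of its
majority partition — cluster allele frequencies integrated against
Beta(1, 1) and mixture weights against a symmetric Dirichlet(1), both in
closed form. This evidence rises when a split separates genuinely distinct
allele-frequency profiles and falls when a homogeneous cluster is split
(the Ockham penalty), mirroring the behaviour of a marginal data
likelihood, and it supports small clusters that predictive (held-out)
scoring penalises; a held-out-likelihood alternative
(`holdout_fraction` in `admixture_fit`) is retained for comparison.

**Alignment and agreement.** Replicate membership matrices are aligned over
cluster-label permutations — exhaustive search for K ≤ 8, greedy
closest-column matching (lowest index first, deterministic) above — and
summarised by H′, the mean over run pairs of 1 − Σ|Q − Q′|/(2n) at the
pair's best permutation. Hard assignments from different methods are
compared by solving the assignment problem on their confusion matrix;
agreement is the percent of samples on the matched diagonal.

**Trees.** Neighbor joining is delegated to scikit-bio; bootstrap support
resamples loci with replacement, recomputes allele-difference distances and
trees, and counts canonical bipartitions. On additive matrices NJ
reproduces the generating topology and branch lengths exactly (tested).

## Quantitative traits

Plants that have not flowered by the experiment end are right-censored:
they receive the end-of-experiment flowering time (default 200 days) and
the leaf number predicted at that time by the least-squares regression of
leaf number on flowering time fitted to flowered plants. Imputation never
alters recorded values. An accession has an obligate vernalization
requirement when none of its unvernalized plants flowered (and, where
vernalized records exist, it did flower under vernalization); regional
proportions are compared by Fisher's exact test.

Q_ST = V_B/(V_B + V_W) from a one-way random-effects decomposition of
per-accession trait values (accessions are the replicates within groups;
plant-level replication is averaged first, though plant-level input is
possible). The haploid-style formula is used as written — no 2V_W
denominator term, which would be the outbred-diploid correction and is not
appropriate for selfing lines treated as haploid. `anova_moments` uses
expected mean squares with the unbalanced n₀; `reml` fits the same model by
restricted maximum likelihood (statsmodels MixedLM); the two agree to 1e−4
on balanced designs (tested). Negative between-group components are
truncated to zero with the raw value retained. A permutation p (group
labels shuffled) is available. Tukey HSD letters come from the standard
insertion algorithm over the rejected pairs.

## Synthetic data

All generators draw from `numpy.random.default_rng(seed)`; the seed is
mandatory, and equal seeds give identical output on any platform.

* **Island model** — ancestral frequencies ~ Uniform(0.05, 0.95) (the
  bounds keep small panels from being dominated by monomorphic draws), deme
  frequencies ~ Beta with the Balding–Nichols parameterisation at
  differentiation F, calls Bernoulli. E[F_ST] = F analytically, which makes
  estimator-recovery targets clean. `selfing_collapse` duplicates existing
  deme haplotypes with the given probability (1.0 fixes each deme on one
  haplotype, the extreme-selfing signature).
* **Hierarchical model** — group frequencies from the ancestral at F_ct,
  population frequencies from their group's at F_sc. The bundled regional
  design uses the published study's shape: 20 populations holding
  2–10 haplotypes each (65 total) in 4 groups, 130 loci, F_ct = 0.431 and
  F_sc = 0.402/(0.402+0.184) = 0.686 taken from the published two-level
  variance shares; simulated AMOVA shares land at ≈ 43/40/18 and total
  F_ST ≈ 0.8, matching the published values.
* **Stepping stone** — deme logit-frequencies follow a random walk along a
  linear transect (step sd 0.6 by default; 0 draws demes independently,
  removing the spatial signal); demes sit 50 km apart along a meridian.
* **Traits** — group effects ~ N(0, V_B), accession residuals ~ N(0, V_W),
  plant noise ~ N(0, plant_sd²) around a baseline (default 100 days), leaf
  number 0.75·FT plus noise, optional right-censoring above a day limit.

What the generators do **not** emulate: linkage disequilibrium between loci
(loci are exchangeable, so the PCA LD correction is exercised structurally,
not validated against real LD), SNP ascertainment bias across the CE/IP/W
panels, genotyping error, non-equilibrium demography (admixture gradients,
range expansions), or correlated allele frequencies between clusters.
Passing tests therefore demonstrate estimator correctness and pipeline
behaviour under the stated models, not robustness to those real-data
features.

## Problem sizes and test design

The suite exercises the estimators at desk scale, chosen to keep the full
run in a few minutes while leaving the statistical targets meaningful:
island-model F_ST recovery at F = 0.3 uses 20 demes × 8 samples × 200 loci
over 50 replicates (bias tolerance ±0.05); Mantel type-I error uses 500
null pairs at n = 15 with 199 permutations (band 3–7% at α = 5%); K
recovery uses 20 datasets at 60 samples × 100 loci with true K ∈ {1,2,3}
(F = 0.5 for the structured cases — this system's published population
differentiation is far stronger still); the regional clustering check runs
K = 1..10 with 20 replicate runs on three seeded datasets of the
hierarchical design. Q_ST recovery spans true values 0.1–0.9 at 20 groups
× 10 accessions × 40 replicates (tolerance ±0.05 on the mean).

## Known limitations

* The admixture model assumes uncorrelated cluster frequencies and no
  linkage model; exact membership proportions from linkage-aware Bayesian
  samplers will differ even where the partition agrees.
* The evidence-ladder K selection scores each run's majority partition, so
  at strong admixture (rows of Q far from the simplex vertices) the
  hard-partition evidence understates model fit; held-out likelihood is the
  provided alternative there.
* AMOVA treats missing calls by pairwise deletion; loci missing in a
  structured pattern could bias components.
* Tracy–Widom p-values rely on moment-matched asymptotics and are
  approximate for very small panels.
* `compare_ibd` requires combined cross-region distance matrices (see
  above), so it cannot consume two disjoint regional studies without the
  joint geography.
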