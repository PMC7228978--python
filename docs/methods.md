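# Methods

This note records the statistical procedures the package implements, the
defaults and why, and what the synthetic generator does and does not show
about real data.

## Study design assumed by the pipeline

The pipeline targets matched case/control 16S cohorts: every case (PWH,
person with HIV) has exactly one seronegative control (SN) matched for
subgroup (F / MSM / MSW), birth country, age and BMI, encoded by a shared
`pair_id`. Per-ASV screens between cases and controls are therefore paired
(Wilcoxon signed-rank); contrasts that cross subgroups (MSM vs MSW,
RAI+ vs RAI−) are unpaired (Mann–Whitney). Samples whose matched partner is
removed by depth filtering are excluded from paired analyses with a logged
warning rather than an error (`complete_pair_samples`).

## Table preparation

- ASV identifiers are md5 digests of the upper-cased 16S sequence. The
  4-character prefix exists only for display; prefixes can collide, so the
  full digest is the only join key.
- ASVs present in fewer than six samples are removed before analysis;
  for any specific two-group screen, ASVs present in fewer than 20% of the
  samples under comparison are additionally removed. Both boundaries are
  inclusive on the "kept" side (an ASV at exactly 20% prevalence is
  retained), since the filters are phrased as "fewer than".
- Rarefaction subsamples each sample to exactly 20,000 reads without
  replacement (multivariate hypergeometric), once per sample with a recorded
  seed; repeated rarefactions are not averaged. Shallower samples are
  dropped and listed.

## Diversity

Shannon entropy uses base 2 (the QIIME2 convention; the base is an option),
richness counts positive taxa, and Faith's PD sums branch lengths over the
union of root-to-tip paths of observed tips, including stems up to the root.
Canberra distance excludes double-zero features and is returned as the raw
sum; an ecology-style variant divides by the number of contributing
features (`normalized=True`). Only the rank order of distances matters for
the permutation tests, so the two variants give identical PERMANOVA
p-values up to ties.

## PERMANOVA with strata

The statistic is Anderson's one-way pseudo-F computed from squared
distances. The permutation null relabels samples; with a strata factor the
relabeling happens independently within each stratum, so matched structure
is preserved under the null. The Monte-Carlo p-value uses the
(+1)/(n_perm+1) convention (the observed arrangement counts as one draw),
with 999 permutations by default; an exhaustive mode enumerates all
distinct within-strata arrangements for small problems and returns the
exact fraction. PCoA is classical scaling of the Gower-centred matrix;
negative eigenvalues (expected for Canberra, which is non-Euclidean) are
reported but not corrected, and their axes are excluded.

## Differential abundance and effect size

Zero pairwise differences are dropped before ranking (Wilcoxon's original
rule) with the effective n recorded; an ASV with no nonzero differences
gets p = 1 and a degenerate flag. Exact null distributions are used for
effective n ≤ 25 without ties, otherwise the normal approximation with
continuity and tie corrections. The effect size is the log₁₀ mean fold
change: zero cells are replaced by 1 (only zero cells — the literal
pseudocount rule; an all-cells variant is available), group means are taken
on the count scale, and the log means are subtracted. BH q-values are
computed per screen.

## Concordance tests

A signature is the set of ASVs passing p < α (strict) or the k smallest
p-values (ties broken by |LMFC| descending, then id), signed by the LMFC.
Overlap between two signatures is reported as a percentage of their union.
Under independent fair signs, the chance that an ASV's direction agrees
across two comparisons is 1/2, and across three is 2/2³ = 1/4; both
fractions are derived in code by enumerating sign vectors rather than
hard-coding. The deviation of observed concordance from the null is tested
two ways and both are always reported: (a) a Fisher's exact test on the
2×2 of observed vs expected concordant/discordant counts, expected counts
being the null fraction of n rounded half-up — the most literal reading of
testing "against an expectation" — and (b) an exact binomial test of the
concordant count against the null fraction, which is the cleaner
formulation. On all instances exercised in the test suite the two agree in
rejection direction.

## Dysbiosis Index

DI = log₁₀ of the ratio of geometric means of case-enriched over
case-depleted taxon counts, computed per sample on the rarefied table. A
pseudocount of 1 is added to every signature-taxon count, not only zeros:
the uniform pseudocount keeps the statistic continuous in the counts and is
the standard geometric-mean convention, while still removing zeros as the
pseudocount is meant to. Geometric means are computed in log space. The
signature is taken from the pipeline's own paired screen (p < 0.05, LMFC
sign), so the DI is reproducible from intermediate artifacts.

## Classifier robustness (RPCV)

Features are per-sample relative abundances' counts filtered at 0.1% mean
relative abundance, transformed log(x+1), then standardized per feature.
The log-before-scale order is adopted because a pseudocount of 1 is only
meaningful on the count scale; scaling first would make it vacuous.
Each of k = 500 iterations draws a stratified random 70/30 split, fits an
L2-penalized logistic model (unit penalty, C = 1; the strength is
configurable and echoed in the report) and scores held-out AUROC. The null
arm permutes labels uniformly at random each iteration — one corrupted
model per real iteration — under the identical protocol. Significance is
the empirical p-value

    p = (#{iterations with real error ≥ mean null error} + 1) / (k + 1),

error = 1 − AUROC: the fraction of real classifiers performing no better
than the averaged permuted classifier, with a finite-sample floor of
1/(k+1). The set-builder form of this formula sometimes displayed in the
literature compares the same two quantities; the prose definition is what
is implemented. A random-forest arm is available behind a flag for
comparison but is not the default.

## Clinical associations

Linear mixed models with a random intercept per subgroup are fit by maximum
likelihood (statsmodels MixedLM) with Wald p-values; REML vs ML makes no
difference to the test conclusions at the panel sizes involved, and ML
keeps likelihoods comparable across fixed-effect specifications. With two
fixed effects both enter jointly. A singular fit (between-subgroup variance
at zero) is flagged and collapses to ordinary regression. Analytes are
z-scaled per column with the sample standard deviation; zero-variance
columns pass through with a warning. The comorbidity count uses the numeric
0/1/≥2 coding treated as numeric. BH adjustment runs across the declared
outcome panel, never post-hoc subsets.

## Synthetic cohort generator

Counts are gamma-Poisson: a lognormal baseline composition (σ = 1.5 on the
log scale) is tilted multiplicatively by natural-log fold effects for HIV
status, MSM membership and recent RAI (applied to RAI+ samples of any sex);
cases' log-composition is additionally scaled by (1 + penalty), a
power-tilt that lowers evenness and hence Shannon diversity. Sequencing
depth is lognormal (mean 40,000 reads, cv ≈ 0.25 — so nearly all samples
survive 20,000-read rarefaction), and each taxon's Poisson rate is
multiplied by a Gamma(1/φ, φ) factor with dispersion φ = 0.5. Defaults
mirror the paired design the pipeline assumes: 18/36/17 pairs (F/MSM/MSW,
142 samples), 300 ASVs, HIV effects of ±1.2 (25 enriched + 25 depleted
taxa), MSM effects of ±1.0 including a 10-taxon overlap with the
HIV-depleted set carrying the opposite sign (enriched in MSM, depleted in
cases), an RAI effect of +0.8 on 15 MSM-signature taxa, and RAI+
probabilities of 0.13 (F), 0.55 (MSM), 0 (MSW).

Each sample's *true* DI is computed from the configured enriched/depleted
sets on the noise-free composition; clinical markers are linear in it plus
Gaussian noise (nadir CD4: 350 − 120·DI ± 80, cases only; pre-ART CD4:
420 − 100·DI ± 110; suPAR: 0.8·DI ± 1 and sCD14: 0.5·DI ± 1 in z-units),
and the comorbidity count thresholds a latent Gaussian (0.9·z(DI) + ε) at
0.8 and 1.6 into {0, 1, ≥2}. The phylogeny is a random binary merge tree
with exponential branch lengths; sequences are random 250-mers.

What the generator does **not** emulate: realistic taxonomies or 16S
sequence structure, taxon-taxon correlation beyond compositional closure,
zero-inflation beyond what gamma-Poisson sampling produces, longitudinal
structure, or covariate-driven confounding (matching is exact by
construction). Passing tests on synthetic cohorts therefore demonstrate
statistical correctness and calibration of the machinery, not biological
validity on real sequencing data.

A compositional caveat worth knowing: because effects act on relative
abundance, enriching a taxon that happens to dominate the baseline
composition depresses every other taxon's relative abundance in cases, and
the ranking of a small planted signature can then be swamped by these
secondary shifts. Parameter-recovery experiments use moderate baselines and
disable the evenness penalty so the planted signature is the only signal.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 40–71 pairs, 120–300 ASVs and depths
of 4,000–20,000 reads, with 500 RPCV iterations where the calibration of
the null arm is itself the quantity under test and 10–60 elsewhere;
permutation tests use 99–999 permutations. Exact tests tolerate ties at
1e-12; PCoA treats eigenvalues below 1e-10 of the spectral radius as zero
and fixes each axis's sign by making its largest-magnitude loading
positive. Degenerate inputs (all-zero count vectors, constant features,
single-class labels, empty signatures) raise informative errors or are
flagged, as documented per function.

## Known limitations

- PERMANOVA is one-way only (no multi-factor partitioning or PERMDISP).
- No compositional (CLR/ALDEx2-style) differential abundance; the paired
  rank tests inherit sensitivity to depth artefacts that rarefaction only
  partially removes.
- UniFrac distances and richness estimators (Chao1/ACE) are out of scope;
  Canberra plus Faith's PD cover the analyses the pipeline automates.
- The ridge penalty is fixed rather than tuned per split by default; an
  internal-CV option would change absolute AUROCs little on well-separated
  cohorts but is not implemented.
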