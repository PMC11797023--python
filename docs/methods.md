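# Methods

## Breeding-system model behind the simulator

The simulator generates the male pool of a polygyne fire-ant population
under these assumptions:

- Every colony holds q reproductive queens, all SB/Sb heterozygotes at the
  social chromosome; q ~ 1 + Poisson(mean − 1) with mean 3.0 by default
  (`QueenNumberModel`). A `fixed=True` switch holds q constant across
  colonies, which is what pedigree-expectation checks need: with variable
  q, the population-mean nestmate relatedness equals 0.5·E[1/q], so the
  implied effective queen number is the *harmonic* mean of q (≈ 2.3 under
  the default model), not its arithmetic mean.
- Fertile males are impaternate haploids. A haploid egg carries Sb with
  probability δ (`distortion_delta`); δ = 0.5 is Mendelian segregation,
  and the default δ = 0.78 reproduces the corrected adult Sb frequency
  observed in the study population.
- Sterile diploid males arise only from matched matings (per-queen
  Bernoulli, rate 0.5 by default) under single-locus complementary sex
  determination: the maternal supergene allele segregates 50:50 and the
  paternal haplotype is drawn from a father pool whose Sb frequency
  defaults to δ (self-consistent with the simulated male pool). The
  per-matched-queen Poisson mean is solved analytically so the expected
  population share of diploids equals `diploid_male_target_fraction`
  (default 0.85, inside the 80–95% range reported for the invasive range).
- Haploid male production per colony is zero-inflated negative binomial
  (defaults: 37.5% of colonies produce none; producers draw NB with mean
  17 and dispersion 0.6). This reproduces the study's sampling structure:
  ~15 of 40 colonies without haploid males, ~10.6 haploid males per colony
  on average, and a heavy tail in which the largest two colonies hold a
  large share of all males. All three parameters are exposed.
- Microsatellite genotypes follow the pedigree: queens and mates carry
  reference-frequency alleles; a haploid son inherits one maternal allele
  per locus; a diploid son adds the father's allele. Nestmate haploid
  relatedness therefore has expectation 0.5/q by construction.
- Weight = group mean + colony effect + residual, in mg. Group means
  default to the published adult averages for haploid Sb (6.12) and SB
  (7.07); the diploid mean (9.0, SD 1.0) is placed above the sampling
  threshold so that the retained diploid sample is weight-truncated, as in
  the study. The colony-effect SD (0.5) and residual SD (0.7) are
  calibration choices: the source analysis reports F-statistics, not
  variance components, so no published decomposition exists to copy. The
  defaults give colony and haplotype ANOVA effects of the same order as
  the published F values.
- Sampling design: every male below 8.0 mg is collected; between 8.0 and
  10.0 mg at most 20 males are kept per 0.25 mg half-open bin (uniformly
  at random); heavier males are dropped. All four numbers are parameters.

What the simulator does **not** emulate: genotyping error and allelic
dropout, linkage between microsatellite loci, non-zero relatedness among
queens or mates, inbreeding (F_IS > 0), colony ontogeny, spatial structure,
and stage-specific weight differences (pupae use the same weight model as
adults). Passing tests therefore demonstrate correctness of the estimators
under clean marker data and idealized kin structure, not robustness to
those real-data complications.

## Ploidy classification

Two Gp-9 products (517 + 423 bp) always yield diploid SB/Sb, regardless of
the microsatellites. For single-band males: any observed heterozygous
microsatellite locus ⇒ diploid (homozygous at the supergene, so SB/SB or
Sb/Sb according to the band); all loci homozygous-appearing ⇒ haploid with
the band's haplotype. Records with a missing microsatellite call are left
`unresolved` and excluded downstream (the missing-data rule is our choice;
the source describes none). The false-haploid probability is the
Hardy–Weinberg all-locus homozygosity product, ≈ 0.53% for the default
panel profile; an optional F_IS term inflates per-locus homozygosity to
F + (1−F)Σp², default F = 0.

## Frequency and weight estimators

- **Pooled**: proportion over all confirmed haploids of a stage; CI from
  5000 bootstrap resamples of individuals (equivalently Binomial(n, p̂)
  draws), 2.5th/97.5th percentiles.
- **Colony-resampled**: 500 independent replicates; each draws one haploid
  male per eligible colony (those containing ≥ 1 haploid male of the
  stage) and computes the SB proportion across colonies; the point
  estimate is the replicate mean. Replicates are independent and a male
  may be drawn in many replicates; within one replicate each colony
  contributes exactly one male. Colonies without eligible males are
  excluded (they contribute no information about haploid haplotypes).
- **Two CIs are reported** for resampled estimates, because the two
  constructions answer different questions. The percentile CI of the 500
  replicate values describes the spread of single-draw proportions — with
  ~25 colonies a replicate moves in steps of ~0.04, so this interval is
  wide by construction. The normal CI on the replicate mean
  (mean ± z·SD/√500) quantifies the precision of the averaged estimate
  and matches the narrow interval style of the corrected published table;
  it is the default `ci_low`/`ci_high`. Calibration checks (does the
  interval cover the true δ?) use the percentile interval, which is the
  construction the resampling procedure literally defines.
- **Weights**: same one-male-per-colony scheme per haplotype (colony
  eligibility is per haplotype, so SB and Sb streams may use different
  colony sets); one-tailed 95% limits are the 5th and 95th percentiles of
  replicate means. The SB−Sb comparison reports the fraction of replicate
  pairs with a non-positive difference; zero is reported as P < 1/n_reps.

## Relatedness and effective queen number

Pairwise r for haploids is Σₗ(sₗ−hₗ)/Σₗ(1−hₗ) with hₗ the reference
expected identity. It is unbiased for pedigree relatedness when the
reference frequencies are correct: brothers average 0.5, unrelated pairs
0. Colony r is the mean over all within-colony pairs (computed in closed
form from per-locus allele tallies); population r is the unweighted mean
of colony values, CI by percentile bootstrap over colonies (5000 draws).
The estimator is a deliberate, documented choice — the published analysis
used an external program without naming its estimator, so exact numerical
agreement with those runs is not claimed; the published r values are used
as *inputs* where needed. Effective queen number is n_e = 0.5/r under
unrelated queens and mates; it is undefined for r ≤ 0 and errors rather
than extrapolating.

## Test battery

Exact binomial (point-probability two-sided ordering) against 0.5;
Fisher's exact 2×2 (same ordering); t-tests (Welch default, Student
optional — the variant is recorded); sequential (type-I) two-way ANOVA of
weight ~ colony + haplotype + interaction with colony entered first. The
published colony df of 16 implies an unstated colony-inclusion rule, so
the operation takes an explicit predicate (default: colonies with ≥ 2
haploid males carrying both haplotypes) and reports the realized df.
Execution-assay proportions use Wilson score intervals by default
(configurable to Clopper–Pearson or bootstrap); contrasts are Fisher
tests for form, ploidy within polygyne, haplotype among haploids, and
genotype among diploids, skipping (with a warning) any contrast with an
empty group.

## Numerical and design choices

- All randomness flows from numpy `default_rng`; pipeline stages derive
  sub-seeds by CRC-hashing the stage name with the master seed, so adding
  a stage never perturbs earlier streams and a run is reproducible from
  one integer.
- Degenerate inputs error loudly (`ParameterError` /
  `TableValidationError`): empty band sets, zero haploids, fewer than two
  eligible colonies, r ≤ 0, constant-weight ANOVA (reported as F = 0,
  p = 1 rather than NaN).
- Validation is total: delimited readers raise typed schema/row errors and
  never coerce silently; per-locus allele frequencies must sum to 1 within
  1e-6 (counts inputs are normalized instead).
- Problem sizes in the test suite (e.g. 200-replicate calibrations at 40
  colonies, 25 simulations per queen number) were chosen to keep
  Monte-Carlo error comfortably below the asserted tolerances while the
  whole suite runs in well under a minute.

## Known limitations

- The classifier takes genotypes as given; no genotyping-error model.
- The misclassification formula assumes locus independence and
  Hardy–Weinberg genotype proportions in the diploid pool.
- The relatedness stage requires externally supplied reference allele
  frequencies; estimates are sensitive to reference misspecification.
- The colony-resampled estimator is undefined with fewer than two
  male-containing colonies, and small eligible-colony counts make its
  replicate distribution coarse.
- The execution-assay module analyses outcome tables; the behavioral
  protocol itself is only simulated.
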