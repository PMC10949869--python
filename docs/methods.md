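# Methods

This note records the statistical model, the estimators, the numerical
choices and their rationale, and the known limitations.  Wherever a
quantity mirrors a published figure, the inputs are the printed group
counts: 47 vaccinated Definite/Probable cases with blood types
(O, A, B, AB) = (20, 22, 2, 3) and 441 unvaccinated controls with
(74, 312, 39, 16).

## Allele-frequency model

ABO phenotypes follow a one-locus, three-allele system with A and B
codominant to each other and both dominant over O.  Under random mating
(Hardy-Weinberg equilibrium, HWE) the phenotype probabilities given
allele frequencies (pA, pB, pO), pA + pB + pO = 1, are

    f(O)  = pO²
    f(A)  = pA² + 2 pA pO
    f(B)  = pB² + 2 pB pO
    f(AB) = 2 pA pB

The likelihood of observed phenotype counts (nO, nA, nB, nAB) is
multinomial in these cell probabilities.

### Gene counting (EM)

`em_abo` maximizes the likelihood by expectation-maximization:

- **E-step** — split the dominant phenotype counts into expected
  genotype counts at the current frequencies:
  E[AA | A] = nA·pA² / (pA² + 2 pA pO), E[AO | A] = nA − E[AA | A], and
  analogously for B.  O and AB phenotypes identify their genotypes.
- **M-step** — count alleles over the 2n gametes:
  pA ← (2·E[AA] + E[AO] + nAB) / 2n, likewise pB; pO is taken as the
  complement 1 − pA − pB so the simplex constraint holds exactly in
  floating point.

Each iteration provably does not decrease the log-likelihood; the
implementation records the trace and raises if it ever drops by more
than 1e-9 (a numerical self-check, not a statistical one).  Convergence
is declared when the max absolute frequency change falls below `tol`
(default 1e-10, default cap 10 000 iterations); non-convergence is
flagged on the result rather than raised.

**Initialization.**  Bernstein's square-root estimator
p' = 1 − √((nO+nB)/n), q' = 1 − √((nO+nA)/n), r' = √(nO/n), floored at
1e-3 and normalized.  The floor is essential, not cosmetic: the simplex
boundary is invariant under the EM map, so a component started at
exactly zero can never leave zero.  With no type-O subjects the raw
Bernstein point has r' = 0, and e.g. counts (0, 1, 1, 0) would stall at
the saddle (pA, pB, pO) = (0.5, 0.5, 0) (log-likelihood −2.77) instead
of the maximizer (⅓, ⅓, ⅓) (−2.20).  Components above the floor are
unchanged.  Validation: on every count vector with n ≤ 12 (1 819
vectors) the EM fixed point matches an independent two-stage grid search
over the simplex (coarse step 2e-3, refinement step 1e-4) to within
2e-4 per component.

A vectorized batch variant (`_em_batch`) runs the same recursion on an
(m, 4) count matrix at once; it powers the bootstrap, the permutation
null and the simulation experiments.

### Bootstrap confidence intervals

`bootstrap_allele_ci` resamples phenotype counts multinomially at the
observed n, re-runs EM on each replicate, and takes percentile
endpoints (default 95%, 10 000 replicates).  Replicates whose EM did
not converge are dropped with a warning if they exceed 1% of draws.
`bootstrap_allele_diff_ci` resamples the two groups independently for
between-group differences.  Empirical check: over 500 simulated
control-sized cohorts, 95% intervals cover the true frequency of every
allele in 91–98% of replicates.

### Permutation test

`permutation_allele_diff` tests the between-group difference of one
allele frequency under the null that group labels are exchangeable.
Shuffling subject labels while keeping group sizes fixed induces a
multivariate hypergeometric distribution on the group-1 phenotype
counts, so the null is sampled directly from that distribution
(`numpy`'s generator) — distributionally identical to explicit label
shuffling and far cheaper.  The p-value uses the add-one estimator
(1 + #{extreme}) / (n_perm + 1); the default tail is two-sided by
absolute difference.  `exact=True` enumerates every count split with
hypergeometric log-pmf weights instead of sampling.  Calibration: the
type-I error at α = 0.05 over 500 null simulations lies in [0.03, 0.07].

**Known red test.**  For the study counts the observed O-allele
difference is 0.201, and exact enumeration (15 484 splits) puts its
two-sided tail probability at 2.428e-3 — the published "p < 0.001" is
not reachable by this test with any seed.  The exact one-sided
(greater) tail is 3.16e-4, and the published interval widths for the
allele-frequency differences are consistent with binomial variance
p(1−p)/2n on gamete counts (z ≈ 3.6, p ≈ 3e-4), so the printed figure
most likely reflects a one-sided test and/or allele-level resampling.
Both alternatives overstate the information in phenotype data (the
dominance of A and B over O hides genotypes), so the package retains
the two-sided subject-level test and the acceptance test asserting
p ≤ 0.001 fails honestly.

## Association statistics

- **Odds ratio (O vs A)**: cross-product of the 2×2 table with Wald
  log-scale confidence interval.  The Haldane-Anscombe 0.5 correction is
  applied only when some cell is zero, and is flagged on the result.
  On the study counts: OR 3.83, 95% CI 1.99–7.39.
- **Chi-square**: Pearson test via `scipy.stats.chi2_contingency`
  (Yates continuity only for 2×2 on request).  The 4×2 blood-type table
  gives p = 1.6e-4.
- **Fisher exact**, **Welch/pooled t from summaries** (Satterthwaite df
  computed explicitly), **Mann-Whitney U** (exact when min(n) ≤ 8 and
  untied): delegated to `scipy.stats` behind a uniform result type.
- **Logistic regression**: own iteratively reweighted least squares.
  Rationale: the contract needs separation detection (|coefficient|
  > 15 with still-rising likelihood), observed-information standard
  errors, and collinear-column diagnostics reported by name — not
  exposed as a single call elsewhere.  `statsmodels` serves as an
  independent oracle in the tests only.  On the saturated one-predictor
  model the slope exponentiates to the crude odds ratio (verified to
  1e-6).
- **Hosmer-Lemeshow**: subjects ranked by fitted probability (stable
  sort), split into near-equal bins, statistic Σ(O−E)²/(E(1−E/n_g)) on
  chi-square with bins − 2 df.  Zero-variance bins are merged into a
  neighbour with a warning; with exactly two usable bins the statistic
  is returned with df = 0 and an undefined (NaN) p-value rather than an
  error.

## Frequency matching

`frequency_match` stratifies on age band × sex.  Age bands are
right-closed at (33, 43, 51, 62) years — quintile-like cuts of the
study's age range — and configurable via `MatchSpec`.  `ratio="max"`
consumes every available control in each stratum that contains cases
(the pool-maximal reading of "as many controls as available", which is
how 82 cases acquire 441 controls at ≈1:5.4).  A numeric ratio targets
round(ratio × cases) controls per stratum and relaxes to the available
pool where short, counting each relaxation as an iteration.  Controls
are never reused; cases in a stratum with no controls are reported
unmatched.  Selection is deterministic given `MatchSpec.seed`.
`match_balance` compares **all** cases against the matched controls
(matched-only comparisons are balanced by construction and would mask a
failed match) using Welch t for age and chi-square for sex.

## Synthetic cohorts and the reference cohort

`CohortSpec` defaults encode the study conditions: 47 cases / 441
controls, allele frequencies (pA, pB, pO) = (0.31, 0.05, 0.64) and
(0.50, 0.07, 0.43), ages 46.2 ± 14.7 and 47.4 ± 15.4 years (normal,
rejection-truncated at ≥ 18), female fractions 0.787 and 0.692, case
severity classes (Definite, Probable) at (0.809, 0.191).  Phenotypes
are drawn as two independent allele draws mapped through dominance —
HWE by construction.  Five named substreams from
`numpy.random.SeedSequence(seed).spawn` keep the draws for phenotypes,
ages and sexes independent and reproducible.

`reference_cohort()` is deterministic (fixed internal seed) and
reproduces every printed margin exactly: the 47 Definite/Probable
ChAdOx1-S cases with phenotypes (20, 22, 2, 3) and 37 women, 35
additional cases of other class/vaccine combinations, and 441 controls
with (74, 312, 39, 16) and 305 women.  Quantities never published at
subject level (exact ages, the extra cases' phenotypes) are synthesized
consistently with the printed summaries; analyses that depend only on
the published margins are exact, analyses of the synthesized fields are
representative.

`recovery_experiment` draws per-replicate phenotype counts multinomially
from the HWE phenotype vector rather than materializing subjects — the
distribution of the EM inputs is identical and the experiments (bias,
coverage) run orders of magnitude faster.  Bias check: mean EM estimate
over 500 replicates at n = 5 000 is within 0.01 of truth per allele at
both study frequency vectors.

## Pipeline

`run_pipeline` executes ingest → filter (Definite/Probable, first
vaccine ChAdOx1-S by default) → optional matching → descriptive table →
contingency statistics → logistic fit → EM + bootstrap per group →
permutation tests → report, logging one line per stage; failures raise
`PipelineError` carrying the stage name and the partial report.
Reports render as JSON, markdown or TSV.  The significance threshold
quoted in reports is 0.01.  Seeds for all stochastic stages derive from
the single configured seed via `SeedSequence` spawning and stay below
2³¹.

## Limitations

- HWE is assumed, not tested, in the estimator (the study population is
  treated as randomly mating at this locus); strong departures would
  bias the genotype split in the E-step.
- The permutation and bootstrap procedures treat subjects as
  exchangeable within group; matching covariates are not re-weighted.
- The reference cohort's subject-level ages and the non-headline cases'
  phenotypes are synthetic (margin-consistent), so only margin-level
  results reproduce published values exactly.
- The adjusted (multivariable) odds ratio of the original analysis is
  not reproducible from printed counts; the package verifies the
  saturated-model identity instead.
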