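# vittabo

Case-control analysis toolkit for ABO blood group and vaccine-induced
immune thrombotic thrombocytopenia (VITT) with cerebral venous
thrombosis.  The package reproduces, from printed summary counts, the
headline statistics of a published comparison between 47 Definite or
Probable VITT cases first vaccinated with ChAdOx1-S and 441 unvaccinated
population controls — most importantly the ABO **allele** frequencies,
which are not observable from blood-type (phenotype) counts and must be
inferred.

## The scientific problem

ABO blood typing reports four phenotypes (O, A, B, AB), but A and B are
dominant over O: a type-A subject may be genotype AA or AO.  Under
Hardy-Weinberg equilibrium the phenotype probabilities are

```
f(O) = pO²        f(A) = pA² + 2·pA·pO
f(AB) = 2·pA·pB   f(B) = pB² + 2·pB·pO
```

and the allele frequencies (pA, pB, pO) are estimated by maximum
likelihood using **gene counting**, an EM algorithm: the E-step splits
the A and B phenotype counts into expected AA/AO and BB/BO genotype
counts at the current frequencies, the M-step counts alleles over the
2n gametes.  Around that estimator the package provides percentile
bootstrap intervals, a permutation test for between-group allele
differences, the classical 2×2/4×2 association statistics, logistic
regression by IRLS, frequency matching of controls to cases, and a
synthetic cohort generator for calibration experiments.

## Worked example

```bash
vittabo analyze --seed 7 --n-boot 2000 --n-perm 1999 --out demo/
```

writes `report.json`, `report.md` and `report.tsv`.  The markdown report
contains, among other tables:

```
| Blood type | Cases n (%) | Controls n (%) |
| --- | --- | --- |
| O | 20 (42.6) | 74 (16.8) |
| A | 22 (46.8) | 312 (70.7) |
| B | 2 (4.3) | 39 (8.8) |
| AB | 3 (6.4) | 16 (3.6) |

Odds ratio (O vs A): 3.83 (95% CI 1.99-7.39)

| Group | Allele | Estimate | CI |
| --- | --- | --- | --- |
| case | A | 31% | 22-42 |
| case | B | 5% | 1-10 |
| case | O | 63% | 51-74 |
| control | A | 50% | 46-54 |
| control | B | 7% | 5-8 |
| control | O | 43% | 39-47 |
```

The same computation from Python:

```python
from vittabo import PhenotypeCounts, em_abo, bootstrap_allele_ci

cases = PhenotypeCounts(nO=20, nA=22, nB=2, nAB=3)
fit = em_abo(cases)
print(fit.freqs)           # pA=0.312, pB=0.054, pO=0.634
print(bootstrap_allele_ci(cases, "O", n_boot=10000, seed=17))
```

Other commands: `vittabo fixture` writes the deterministic 523-subject
reference cohort as CSV, `vittabo simulate` draws cohorts from arbitrary
allele frequencies and demographics, `vittabo match` frequency-matches a
control pool to cases by age band and sex.

## Known discrepancy

The published analysis reports the between-group O-allele difference as
significant at p < 0.001 by permutation test.  Shuffling subjects
between the groups (two-sided, by absolute difference) has an exactly
enumerable null here, and the observed difference of 0.201 sits at tail
probability 2.43 × 10⁻³ — above the printed threshold.  The one-sided
tail is 3.2 × 10⁻⁴, and the published confidence-interval widths imply
allele-count rather than subject-level variance, so the printed figure
is likely one-sided and/or computed on gamete units.  The package keeps
the two-sided subject-level test (the defensible default) and the
corresponding acceptance test fails honestly rather than being adjusted
to pass.  Details in [docs/methods.md](docs/methods.md).

## Layout

| Module | Contents |
| --- | --- |
| `vittabo.cohort` | Subject model, CSV I/O, validation, phenotype tabulation |
| `vittabo.alleles` | EM gene counting, bootstrap CIs, permutation test |
| `vittabo.stats` | Odds ratios, chi-square/Fisher/t/U tests, IRLS logistic regression, Hosmer-Lemeshow |
| `vittabo.matching` | Frequency matching by age band × sex |
| `vittabo.simulate` | Synthetic cohorts, reference cohort, calibration experiments |
| `vittabo.pipeline` / `vittabo.cli` | End-to-end analysis pipeline and `vittabo` command |
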