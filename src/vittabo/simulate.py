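"""Synthetic two-group CVT cohorts with HWE ABO genotypes.

The generator draws, per subject, two ABO alleles independently from the
group's allele frequencies (Hardy-Weinberg equilibrium) and maps the
genotype to a phenotype by ABO dominance (A and B codominant over each
other, both dominant over O).  Ages are Normal, truncated at the
inclusion minimum of 18 years by rejection; sex is Bernoulli on the
group's female proportion; cases receive a VITT classification.

Defaults encode the study conditions of the motivating VITT-CVT
case-control analysis: 47 Definite/Probable vaccinated cases versus 441
unvaccinated controls, case allele frequencies (pA, pB, pO) =
(0.31, 0.05, 0.64) and control frequencies (0.50, 0.07, 0.43), ages
46.2 +/- 14.7 vs 47.4 +/- 15.4 years, female proportions 0.787 vs 0.692.

One master seed is split into named substreams (genotypes, ages, sexes,
classes) so adding a field never perturbs the other draws.

:func:`reference_cohort` returns a deterministic 523-subject cohort
whose tabulations reproduce that study's printed margins exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from vittabo.alleles import AlleleFrequencies, _em_batch, bootstrap_allele_ci, hwe_phenotype_freqs
from vittabo.cohort import COVARIATE_NAMES, PHENOTYPES, VITT_CLASSES, Subject

_CASE_FREQS = AlleleFrequencies(0.31, 0.05, 0.64)
_CONTROL_FREQS = AlleleFrequencies(0.50, 0.07, 0.43)


@dataclass
class CohortSpec:
    """Parameters of a simulated two-group cohort (defaults: study conditions)."""

    n_cases: int = 47
    n_controls: int = 441
    case_freqs: AlleleFrequencies = _CASE_FREQS
    control_freqs: AlleleFrequencies = _CONTROL_FREQS
    age_mean_case: float = 46.2
    age_sd_case: float = 14.7
    age_mean_control: float = 47.4
    age_sd_control: float = 15.4
    female_prop_case: float = 0.787
    female_prop_control: float = 0.692
    vitt_class_probs: tuple = (0.809, 0.191, 0.0, 0.0)  # Definite, Probable, Possible, Unlikely
    covariate_prevalences: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")
        probs = np.asarray(self.vitt_class_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("vitt_class_probs must be a probability vector over the four classes")
        for p in (self.female_prop_case, self.female_prop_control):
            if not 0 <= p <= 1:
                raise ValueError("female proportions must lie in [0, 1]")
        for sd in (self.age_sd_case, self.age_sd_control):
            if sd <= 0:
                raise ValueError("age SDs must be positive")
        unknown = set(self.covariate_prevalences) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


def _draw_phenotypes(rng: np.random.Generator, n: int, freqs: AlleleFrequencies) -> list:
    """Two independent allele draws per subject, mapped by dominance."""
    alleles = rng.choice(3, size=(n, 2), p=freqs.as_array())  # 0=A, 1=B, 2=O
    out = []
    for a1, a2 in alleles:
        pair = {a1, a2}
        if pair == {2}:
            out.append("O")
        elif pair == {0, 1}:
            out.append("AB")
        elif 0 in pair:
            out.append("A")
        else:
            out.append("B")
    return out


def _truncated_ages(rng: np.random.Generator, n: int, mean: float, sd: float, floor: float = 18.0) -> np.ndarray:
    """Normal ages, rejection-sampled above the inclusion floor."""
    ages = rng.normal(mean, sd, size=n)
    while True:
        bad = ages < floor
        if not bad.any():
            return ages
        ages[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def simulate_cohort(spec: CohortSpec) -> list:
    """Simulate a two-group cohort of :class:`Subject` rows.

    Deterministic given ``spec.seed``.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_geno, rng_age, rng_sex, rng_class, rng_cov = (np.random.default_rng(s) for s in streams)

    subjects = []
    for group, n, freqs, age_mu, age_sd, fem in (
        ("case", spec.n_cases, spec.case_freqs, spec.age_mean_case, spec.age_sd_case, spec.female_prop_case),
        ("control", spec.n_controls, spec.control_freqs, spec.age_mean_control, spec.age_sd_control,
         spec.female_prop_control),
    ):
        phenos = _draw_phenotypes(rng_geno, n, freqs)
        ages = _truncated_ages(rng_age, n, age_mu, age_sd)
        sexes = np.where(rng_sex.random(n) < fem, "female", "male")
        if group == "case":
            classes = rng_class.choice(VITT_CLASSES, size=n, p=np.asarray(spec.vitt_class_probs))
        covs = {
            name: rng_cov.random(n) < prev
            for name, prev in spec.covariate_prevalences.items()
        }
        for i in range(n):
            subjects.append(
                Subject(
                    id=f"{group}-{i+1:04d}",
                    group=group,
                    age_years=float(ages[i]),
                    sex=str(sexes[i]),
                    abo_phenotype=phenos[i],
                    vitt_class=str(classes[i]) if group == "case" else None,
                    first_vaccine="ChAdOx1-S" if group == "case" else None,
                    covariates={k: int(v[i]) for k, v in covs.items()},
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# Deterministic reference cohort reproducing the study's printed margins.
# ---------------------------------------------------------------------------

# ChAdOx1-S Definite/Probable cases, phenotype margin (O, A, B, AB).
_REF_CASE_DP_PHENO = (20, 22, 2, 3)
_REF_CASE_DP_CLASSES = (("Definite", 38), ("Probable", 9))
_REF_CASE_DP_FEMALE = 37
# Remaining 35 cases: 12 ChAdOx1-S (Possible 5, Unlikely 7) and 23 on
# another first-dose vaccine (Definite 4, Possible 3, Unlikely 16).  Their
# blood types are synthetic -- assigned proportional to the Definite/
# Probable margin -- and excluded from every published-margin check.
_REF_CASE_OTHER = (
    ("ChAdOx1-S", "Possible", 5),
    ("ChAdOx1-S", "Unlikely", 7),
    ("non-ChAdOx1-S", "Definite", 4),
    ("non-ChAdOx1-S", "Possible", 3),
    ("non-ChAdOx1-S", "Unlikely", 16),
)
_REF_CASE_OTHER_PHENO = (15, 16, 2, 2)  # largest-remainder split of 35 by (20,22,2,3)/47
_REF_CASE_TOTAL_FEMALE = 57
_REF_CONTROL_PHENO = (74, 312, 39, 16)
_REF_CONTROL_FEMALE = 305
_REF_SEED = 20230947  # fixed: the reference cohort is a constant dataset


def _margin_labels(margin: Sequence[int]) -> list:
    out = []
    for p, k in zip(PHENOTYPES, margin):
        out.extend([p] * k)
    return out


def _interleave(labels: list, rng: np.random.Generator) -> list:
    """Deterministic shuffle so margins stay exact but order is unpatterned."""
    labels = list(labels)
    rng.shuffle(labels)
    return labels


def reference_cohort() -> list:
    """Deterministic 523-subject cohort matching the study's printed margins.

    47 Definite/Probable ChAdOx1-S cases with phenotype counts
    (O, A, B, AB) = (20, 22, 2, 3); 441 controls with (74, 312, 39, 16);
    35 further cases covering the remaining VITT-class/vaccine margins,
    whose blood types are synthetic (proportional fill).  Sex counts and
    truncated-Normal ages are consistent with the study's summary rows.
    Repeated calls return identical cohorts.
    """
    rng = np.random.default_rng(_REF_SEED)
    subjects = []

    # --- 47 Definite/Probable ChAdOx1-S cases ---
    phenos = _interleave(_margin_labels(_REF_CASE_DP_PHENO), rng)
    classes = _interleave([c for c, k in _REF_CASE_DP_CLASSES for _ in range(k)], rng)
    sexes = _interleave(["female"] * _REF_CASE_DP_FEMALE + ["male"] * (47 - _REF_CASE_DP_FEMALE), rng)
    ages = _truncated_ages(rng, 47, 46.2, 14.7)
    for i in range(47):
        subjects.append(Subject(
            id=f"case-{i+1:04d}", group="case", age_years=float(ages[i]), sex=sexes[i],
            abo_phenotype=phenos[i], vitt_class=classes[i], first_vaccine="ChAdOx1-S"))

    # --- 35 remaining cases (synthetic blood types) ---
    vac_class = [(v, c) for v, c, k in _REF_CASE_OTHER for _ in range(k)]
    phenos = _interleave(_margin_labels(_REF_CASE_OTHER_PHENO), rng)
    n_female = _REF_CASE_TOTAL_FEMALE - _REF_CASE_DP_FEMALE
    sexes = _interleave(["female"] * n_female + ["male"] * (35 - n_female), rng)
    ages = _truncated_ages(rng, 35, 49.9, 15.4)  # completes the overall case mean near 47.8
    for i in range(35):
        vaccine, vclass = vac_class[i]
        subjects.append(Subject(
            id=f"case-{i+48:04d}", group="case", age_years=float(ages[i]), sex=sexes[i],
            abo_phenotype=phenos[i], vitt_class=vclass, first_vaccine=vaccine))

    # --- 441 controls ---
    phenos = _interleave(_margin_labels(_REF_CONTROL_PHENO), rng)
    sexes = _interleave(["female"] * _REF_CONTROL_FEMALE + ["male"] * (441 - _REF_CONTROL_FEMALE), rng)
    ages = _truncated_ages(rng, 441, 47.4, 15.4)
    for i in range(441):
        subjects.append(Subject(
            id=f"control-{i+1:04d}", group="control", age_years=float(ages[i]), sex=sexes[i],
            abo_phenotype=phenos[i]))
    return subjects


def recovery_experiment(
    truth: CohortSpec,
    n_reps: int,
    seed: int = 0,
    ci_level: float = 0.95,
    n_boot: Optional[int] = None,
) -> dict:
    """Parameter-recovery harness for the EM estimator.

    Simulates ``n_reps`` cohorts at the true allele frequencies, re-runs
    gene counting per group per replicate, and reports per-allele bias,
    SD and RMSE.  With ``n_boot`` set, also measures empirical coverage
    of the percentile-bootstrap CI at ``ci_level`` (on the case group).
    Phenotype margins are drawn multinomially from the HWE phenotype
    probabilities -- the same distribution a full subject-level draw
    induces on the counts.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    report: dict = {"n_reps": n_reps, "seed": seed, "groups": {}}
    for group, n, freqs in (("case", truth.n_cases, truth.case_freqs),
                            ("control", truth.n_controls, truth.control_freqs)):
        if n == 0:
            continue
        f = hwe_phenotype_freqs(freqs)
        counts = rng.multinomial(n, f, size=n_reps)
        est, conv = _em_batch(counts)
        est = est[conv]
        true_vec = freqs.as_array()  # (pA, pB, pO)
        bias = est.mean(axis=0) - true_vec
        sd = est.std(axis=0, ddof=1) if len(est) > 1 else np.full(3, np.nan)
        rmse = np.sqrt(((est - true_vec) ** 2).mean(axis=0))
        report["groups"][group] = {
            "n": n,
            "truth": {"pA": true_vec[0], "pB": true_vec[1], "pO": true_vec[2]},
            "bias": dict(zip(("pA", "pB", "pO"), bias.tolist())),
            "sd": dict(zip(("pA", "pB", "pO"), sd.tolist())),
            "sd_defined": n_reps > 1,
            "rmse": dict(zip(("pA", "pB", "pO"), rmse.tolist())),
            "n_converged": int(conv.sum()),
        }
    if n_boot is not None:
        from vittabo.cohort import PhenotypeCounts

        f = hwe_phenotype_freqs(truth.case_freqs)
        hits = {a: 0 for a in ("A", "B", "O")}
        total = 0
        for rep in range(n_reps):
            counts = rng.multinomial(truth.n_cases, f)
            if counts.sum() == 0:
                continue
            pc = PhenotypeCounts(*map(int, counts))
            total += 1
            for allele, true_val in (("A", truth.case_freqs.pA), ("B", truth.case_freqs.pB),
                                     ("O", truth.case_freqs.pO)):
                ci = bootstrap_allele_ci(pc, allele, n_boot=n_boot, level=ci_level,
                                         seed=int(rng.integers(2**31 - 1)))
                if ci.lower <= true_val <= ci.upper:
                    hits[allele] += 1
        report["coverage"] = {a: hits[a] / total for a in hits}
        report["coverage_level"] = ci_level
        report["n_boot"] = n_boot
    return report
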