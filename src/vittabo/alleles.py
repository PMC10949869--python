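"""ABO allele-frequency inference by EM gene counting under HWE.

The ABO locus has three alleles (A, B, O); A and B are codominant and
both dominant over O, so the four observable phenotypes collapse six
genotypes: phenotype A = {AA, AO}, B = {BB, BO}, AB = {AB}, O = {OO}.
Under Hardy-Weinberg equilibrium the phenotype probabilities given
allele frequencies (pA, pB, pO) are

    fO = pO^2,  fA = pA^2 + 2 pA pO,  fB = pB^2 + 2 pB pO,  fAB = 2 pA pB.

Gene counting is the classical EM scheme for this model: the E-step
splits the dominant phenotype counts into expected genotype counts at
the current frequencies, the M-step re-counts alleles from those
expected genotypes.  Each sweep cannot decrease the multinomial
log-likelihood, and the fixed point is the maximum-likelihood estimate.

Uncertainty is attached by percentile bootstrap (multinomial resampling
of the phenotype counts), and between-group frequency differences are
tested against a permutation null that shuffles group labels while
preserving group sizes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln

from vittabo.cohort import PHENOTYPES, PhenotypeCounts

_SIMPLEX_TOL = 1e-9
ALLELES = ("A", "B", "O")


@dataclass(frozen=True)
class AlleleFrequencies:
    """A point on the (A, B, O) allele-frequency simplex."""

    pA: float
    pB: float
    pO: float

    def __post_init__(self) -> None:
        for name in ("pA", "pB", "pO"):
            v = getattr(self, name)
            if v < -_SIMPLEX_TOL or v > 1 + _SIMPLEX_TOL:
                raise ValueError(f"{name}={v} outside [0, 1]")
            object.__setattr__(self, name, min(max(v, 0.0), 1.0))
        if abs(self.pA + self.pB + self.pO - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"frequencies sum to {self.pA + self.pB + self.pO}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.pA, self.pB, self.pO])

    def __getitem__(self, allele: str) -> float:
        return {"A": self.pA, "B": self.pB, "O": self.pO}[allele]


@dataclass(frozen=True)
class GenotypeExpectation:
    """Expected genotype counts given phenotype counts and frequencies."""

    eAA: float
    eAO: float
    eBB: float
    eBO: float
    eAB: float
    eOO: float


@dataclass
class EMResult:
    freqs: AlleleFrequencies
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pA": self.freqs.pA, "pB": self.freqs.pB, "pO": self.freqs.pO,
                "loglik": self.loglik, "n_iter": self.n_iter, "converged": self.converged,
            }
        )


@dataclass
class IntervalEstimate:
    """Percentile-bootstrap interval for one allele frequency."""

    point: float
    lower: float
    upper: float
    level: float
    method: str
    n_boot: int
    seed: int
    n_dropped: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class PermutationResult:
    observed_diff: float
    p_value: float
    n_perm: int
    seed: Optional[int]
    tail: str
    n_redrawn: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def hwe_phenotype_freqs(freqs: AlleleFrequencies) -> np.ndarray:
    """Phenotype probability vector (O, A, B, AB) under HWE."""
    pA, pB, pO = freqs.pA, freqs.pB, freqs.pO
    return np.array([pO * pO, pA * pA + 2 * pA * pO, pB * pB + 2 * pB * pO, 2 * pA * pB])


# Lower bound for initial allele frequencies: the EM map fixes any
# component that starts at exactly zero, so initialization must be interior.
_INIT_FLOOR = 1e-3


def bernstein_init(counts: PhenotypeCounts) -> AlleleFrequencies:
    """Square-root (Bernstein) initializer for ABO gene counting.

    p' = 1 - sqrt((nO+nB)/n), q' = 1 - sqrt((nO+nA)/n), r' = sqrt(nO/n),
    floored at a small interior value and normalized to the simplex.
    The floor (1e-3) matters: the simplex boundary is invariant under the
    EM map, so a component started at exactly zero can never move off it
    even when the likelihood maximizer is interior (e.g. one A plus one B
    subject, whose MLE is the uniform point despite nO = 0).
    """
    n = counts.n
    if n == 0:
        raise ValueError("cannot initialize from an empty sample")
    p = 1.0 - math.sqrt((counts.nO + counts.nB) / n)
    q = 1.0 - math.sqrt((counts.nO + counts.nA) / n)
    r = math.sqrt(counts.nO / n)
    v = np.clip([p, q, r], _INIT_FLOOR, None)
    v = v / v.sum()
    return AlleleFrequencies(v[0], v[1], v[2])


def e_step(counts: PhenotypeCounts, freqs: AlleleFrequencies) -> GenotypeExpectation:
    """Split dominant phenotype counts into expected genotype counts."""
    pA, pB, pO = freqs.pA, freqs.pB, freqs.pO
    fA = pA * pA + 2 * pA * pO
    fB = pB * pB + 2 * pB * pO
    if counts.nA > 0 and fA == 0:
        raise ValueError("phenotype A observed but has zero probability under the model")
    if counts.nB > 0 and fB == 0:
        raise ValueError("phenotype B observed but has zero probability under the model")
    eAA = counts.nA * pA * pA / fA if counts.nA > 0 else 0.0
    eBB = counts.nB * pB * pB / fB if counts.nB > 0 else 0.0
    return GenotypeExpectation(
        eAA=eAA, eAO=counts.nA - eAA,
        eBB=eBB, eBO=counts.nB - eBB,
        eAB=float(counts.nAB), eOO=float(counts.nO),
    )


def m_step(expect: GenotypeExpectation, n: int) -> AlleleFrequencies:
    """Re-count alleles from expected genotype counts (2n gametes).

    pO is computed as the complement so the result sums to 1 exactly.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    two_n = 2.0 * n
    pA = (2 * expect.eAA + expect.eAO + expect.eAB) / two_n
    pB = (2 * expect.eBB + expect.eBO + expect.eAB) / two_n
    return AlleleFrequencies(pA, pB, 1.0 - pA - pB)


def multinomial_loglik(counts: PhenotypeCounts, freqs: AlleleFrequencies) -> float:
    """Multinomial log-likelihood sum(n_k log f_k) of the phenotype counts.

    The multinomial coefficient is omitted (constant in the frequencies).
    Returns ``-inf`` with a warning when a positive count meets a zero
    model probability.
    """
    f = hwe_phenotype_freqs(freqs)
    n = counts.as_array()
    if np.any((n > 0) & (f <= 0)):
        warnings.warn("positive phenotype count with zero model probability; log-likelihood is -inf")
        return -math.inf
    mask = n > 0
    return float(np.sum(n[mask] * np.log(f[mask])))


def em_abo(
    counts: PhenotypeCounts,
    tol: float = 1e-10,
    max_iter: int = 10000,
    init: Optional[AlleleFrequencies] = None,
) -> EMResult:
    """Maximum-likelihood ABO allele frequencies by gene counting.

    Alternates :func:`e_step` / :func:`m_step` from the Bernstein
    initializer (or ``init``) until the largest absolute frequency change
    drops below ``tol``.  The log-likelihood trace is recorded and
    checked for monotonicity on every call; non-convergence within
    ``max_iter`` flags the result rather than raising.
    """
    if counts.n == 0:
        raise ValueError("cannot estimate frequencies from an empty sample")
    if tol <= 0:
        raise ValueError("tol must be positive")
    freqs = init if init is not None else bernstein_init(counts)
    trace = [multinomial_loglik(counts, freqs)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = m_step(e_step(counts, freqs), counts.n)
        trace.append(multinomial_loglik(counts, new))
        if trace[-1] < trace[-2] - 1e-9:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {trace[-2]} -> {trace[-1]}"
            )
        delta = np.max(np.abs(new.as_array() - freqs.as_array()))
        freqs = new
        if delta < tol:
            converged = True
            break
    return EMResult(freqs=freqs, loglik=trace[-1], n_iter=it, converged=converged, loglik_trace=trace)


# ---------------------------------------------------------------------------
# Vectorized gene counting over many count vectors at once.  Used by the
# bootstrap and permutation machinery, where thousands of small EM runs
# are needed; each row of `counts` is an (O, A, B, AB) vector.
# ---------------------------------------------------------------------------

def _em_batch(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 10000):
    """Run gene counting on every row of an (m, 4) count matrix.

    Returns ``(freqs, converged)`` where ``freqs`` is (m, 3) in
    (pA, pB, pO) order.  Rows with zero total are returned as NaN and
    marked non-converged.
    """
    counts = np.asarray(counts, dtype=float)
    nO, nA, nB, nAB = counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3]
    n = counts.sum(axis=1)
    ok = n > 0
    nsafe = np.where(ok, n, 1.0)

    # Bernstein initializer, vectorized, with the same interior floor as
    # :func:`bernstein_init` (a component at exactly zero never moves).
    p = np.clip(1.0 - np.sqrt((nO + nB) / nsafe), _INIT_FLOOR, None)
    q = np.clip(1.0 - np.sqrt((nO + nA) / nsafe), _INIT_FLOOR, None)
    r = np.clip(np.sqrt(nO / nsafe), _INIT_FLOOR, None)
    total = p + q + r
    pA = p / total
    pB = q / total

    converged = np.zeros(len(counts), dtype=bool)
    active = ok.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        pO = 1.0 - pA - pB
        fA = pA * pA + 2 * pA * pO
        fB = pB * pB + 2 * pB * pO
        eAA = np.where(fA > 0, nA * pA * pA / np.where(fA > 0, fA, 1.0), 0.0)
        eBB = np.where(fB > 0, nB * pB * pB / np.where(fB > 0, fB, 1.0), 0.0)
        new_pA = (2 * eAA + (nA - eAA) + nAB) / (2 * nsafe)
        new_pB = (2 * eBB + (nB - eBB) + nAB) / (2 * nsafe)
        delta = np.maximum(np.abs(new_pA - pA), np.abs(new_pB - pB))
        pA = np.where(active, new_pA, pA)
        pB = np.where(active, new_pB, pB)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly

    freqs = np.column_stack([pA, pB, 1.0 - pA - pB])
    freqs[~ok] = np.nan
    return freqs, converged


_ALLELE_INDEX = {"A": 0, "B": 1, "O": 2}


def bootstrap_allele_ci(
    counts: PhenotypeCounts,
    allele: str,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> IntervalEstimate:
    """Percentile-bootstrap CI for one allele frequency.

    Phenotype counts are resampled multinomially (size n, probabilities
    equal to the observed proportions) and gene counting is re-run per
    replicate.  Replicates where EM fails to converge are dropped and
    counted; more than 1% drops triggers a warning.  Deterministic given
    ``seed``.
    """
    if allele not in _ALLELE_INDEX:
        raise ValueError(f"unknown allele {allele!r}")
    if counts.n == 0:
        raise ValueError("empty sample")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    props = counts.as_array() / counts.n
    resampled = rng.multinomial(counts.n, props, size=n_boot)
    freqs, conv = _em_batch(resampled)
    values = freqs[conv, _ALLELE_INDEX[allele]]
    n_dropped = int(n_boot - conv.sum())
    if n_dropped > 0.01 * n_boot:
        warnings.warn(f"{n_dropped}/{n_boot} bootstrap replicates dropped (EM non-convergence)")
    alpha = 1.0 - level
    lower, upper = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    point = em_abo(counts).freqs[allele]
    if not (lower <= point <= upper):
        warnings.warn(
            f"percentile interval [{lower:.4f}, {upper:.4f}] does not bracket the point "
            f"estimate {point:.4f}; the estimate sits outside the resampling hull"
        )
    return IntervalEstimate(
        point=point, lower=float(lower), upper=float(upper), level=level,
        method="percentile-bootstrap", n_boot=n_boot, seed=seed, n_dropped=n_dropped,
    )


def bootstrap_allele_diff_ci(
    counts1: PhenotypeCounts,
    counts2: PhenotypeCounts,
    allele: str,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> IntervalEstimate:
    """Percentile-bootstrap CI for a between-group allele-frequency difference.

    Both groups are resampled independently (multinomial at their observed
    proportions and sizes); gene counting is re-run per replicate and the
    percentile interval of ``freq1[allele] - freq2[allele]`` is returned.
    """
    if allele not in _ALLELE_INDEX:
        raise ValueError(f"unknown allele {allele!r}")
    if counts1.n == 0 or counts2.n == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    j = _ALLELE_INDEX[allele]
    r1 = rng.multinomial(counts1.n, counts1.as_array() / counts1.n, size=n_boot)
    r2 = rng.multinomial(counts2.n, counts2.as_array() / counts2.n, size=n_boot)
    f1, c1 = _em_batch(r1)
    f2, c2 = _em_batch(r2)
    good = c1 & c2
    diffs = f1[good, j] - f2[good, j]
    n_dropped = int(n_boot - good.sum())
    if n_dropped > 0.01 * n_boot:
        warnings.warn(f"{n_dropped}/{n_boot} bootstrap replicates dropped (EM non-convergence)")
    alpha = 1.0 - level
    lower, upper = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    point = em_abo(counts1).freqs[allele] - em_abo(counts2).freqs[allele]
    return IntervalEstimate(
        point=float(point), lower=float(lower), upper=float(upper), level=level,
        method="percentile-bootstrap", n_boot=n_boot, seed=seed, n_dropped=n_dropped,
    )


def counts_from_phenotypes(phenotypes: Sequence[str]) -> PhenotypeCounts:
    """Tally a sequence of phenotype labels into :class:`PhenotypeCounts`."""
    tally = {p: 0 for p in PHENOTYPES}
    for p in phenotypes:
        if p not in tally:
            raise ValueError(f"unknown phenotype {p!r}")
        tally[p] += 1
    return PhenotypeCounts(tally["O"], tally["A"], tally["B"], tally["AB"])


def _coerce_counts(x: Union[PhenotypeCounts, Sequence[str]]) -> PhenotypeCounts:
    return x if isinstance(x, PhenotypeCounts) else counts_from_phenotypes(x)


def _log_mvhg_pmf(k: np.ndarray, pool: np.ndarray, draw: int) -> float:
    """log multivariate-hypergeometric pmf of split ``k`` from ``pool``."""
    n = pool.sum()

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return float(np.sum(logc(pool, k)) - logc(n, draw))


def permutation_allele_diff(
    group1: Union[PhenotypeCounts, Sequence[str]],
    group2: Union[PhenotypeCounts, Sequence[str]],
    allele: str,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "two-sided",
    exact: bool = False,
) -> PermutationResult:
    """Permutation test for a between-group allele-frequency difference.

    The observed statistic is ``em(group1)[allele] - em(group2)[allele]``.
    The null pools both groups' phenotypes and shuffles group labels
    while preserving group sizes; gene counting is re-run per shuffle.
    (Resampling the group-1 counts from the pooled counts by multivariate
    hypergeometric draws is exactly the label-shuffling distribution.)

    Monte Carlo p-values use the add-one estimator
    ``p = (1 + #extreme) / (n_perm + 1)``.  With ``exact=True`` all
    distinct count splits are enumerated with their hypergeometric
    weights and the p-value is the exact null tail probability.
    """
    if allele not in _ALLELE_INDEX:
        raise ValueError(f"unknown allele {allele!r}")
    if tail not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    c1, c2 = _coerce_counts(group1), _coerce_counts(group2)
    if c1.n == 0 or c2.n == 0:
        raise ValueError("both groups must be nonempty")
    j = _ALLELE_INDEX[allele]
    observed = em_abo(c1).freqs[allele] - em_abo(c2).freqs[allele]
    pool = (c1.as_array() + c2.as_array()).astype(int)
    n1 = c1.n

    def is_extreme(diffs: np.ndarray) -> np.ndarray:
        eps = 1e-12
        if tail == "two-sided":
            return np.abs(diffs) >= abs(observed) - eps
        if tail == "greater":
            return diffs >= observed - eps
        return diffs <= observed + eps

    if exact:
        # Enumerate all splits (kO, kA, kB, kAB) of the pooled counts.
        splits = [
            (kO, kA, kB, n1 - kO - kA - kB)
            for kO in range(min(pool[0], n1) + 1)
            for kA in range(min(pool[1], n1 - kO) + 1)
            for kB in range(min(pool[2], n1 - kO - kA) + 1)
            if 0 <= n1 - kO - kA - kB <= pool[3]
        ]
        k = np.array(splits, dtype=float)
        f1, _ = _em_batch(k)
        f2, _ = _em_batch(pool[None, :] - k)
        diffs = f1[:, j] - f2[:, j]
        logw = np.array([_log_mvhg_pmf(row, pool, n1) for row in k])
        w = np.exp(logw - logw.max())
        w /= w.sum()
        p = float(np.sum(w[is_extreme(diffs)]))
        return PermutationResult(
            observed_diff=float(observed), p_value=min(p, 1.0),
            n_perm=len(splits), seed=None, tail=tail,
        )

    rng = np.random.default_rng(seed)
    n_redrawn = 0
    diffs = np.empty(0)
    needed = n_perm
    for _round in range(6):
        k = rng.multivariate_hypergeometric(pool, n1, size=needed).astype(float)
        f1, conv1 = _em_batch(k)
        f2, conv2 = _em_batch(pool[None, :] - k)
        good = conv1 & conv2
        diffs = np.concatenate([diffs, (f1[:, j] - f2[:, j])[good]])
        n_redrawn += int(needed - good.sum())
        needed = n_perm - len(diffs)
        if needed <= 0:
            break
    if len(diffs) < n_perm:
        raise RuntimeError(f"could not complete {n_perm} permutations ({len(diffs)} usable)")
    diffs = diffs[:n_perm]
    p = (1.0 + int(is_extreme(diffs).sum())) / (n_perm + 1.0)
    return PermutationResult(
        observed_diff=float(observed), p_value=p, n_perm=n_perm,
        seed=seed, tail=tail, n_redrawn=n_redrawn,
    )
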