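"""Iterative frequency matching of controls to cases by age band and sex.

Frequency matching selects controls so that their distribution over
strata mirrors the cases' distribution, without 1:1 pairing.  Strata
are the cross of right-closed age bands and sex.  The default bands are
the study's: <=33, (33, 43], (43, 51], (51, 62], >62 years.

Within a stratum, controls are drawn uniformly at random without
replacement from a dedicated seeded stream, so matching randomness
never interacts with simulation seeds.  When a stratum's control pool
cannot meet the target ratio the target is relaxed for that stratum
(never the age-band/sex equality itself), stratum by stratum in order
of deficit; each relaxation counts as one extra iteration.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from vittabo.cohort import Subject
from vittabo.stats import TestResult, chisq_test, t_test_from_summary
from vittabo.cohort import ContingencyTable

DEFAULT_AGE_EDGES = (33.0, 43.0, 51.0, 62.0)


@dataclass(frozen=True)
class MatchSpec:
    """Matching strata: right-closed age bands x sex, plus a seed.

    ``age_edges`` are the interior cut points; the first band is
    left-unbounded and the last right-unbounded, so every age falls in
    exactly one band.  Ages exactly on an edge go to the lower band.
    """

    age_edges: tuple = DEFAULT_AGE_EDGES
    sex_levels: tuple = ("female", "male")
    seed: int = 0

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.age_edges)
        if list(edges) != sorted(set(edges)):
            raise ValueError("age_edges must be strictly increasing")
        object.__setattr__(self, "age_edges", edges)

    def age_bin(self, age: float) -> int:
        # Right-closed: age == edge goes to the lower band.
        return bisect_left(self.age_edges, age)

    def bin_label(self, i: int) -> str:
        e = self.age_edges
        if i == 0:
            return f"<={e[0]:g}"
        if i == len(e):
            return f">{e[-1]:g}"
        return f"({e[i-1]:g},{e[i]:g}]"

    def stratum(self, subject: Subject) -> tuple:
        if subject.sex not in self.sex_levels:
            raise ValueError(f"sex {subject.sex!r} not in matching levels")
        return (self.age_bin(subject.age_years), subject.sex)


@dataclass
class MatchResult:
    assignments: dict
    unmatched_cases: list
    iterations_used: int
    bin_occupancy: dict = field(default_factory=dict)

    @property
    def matched_control_ids(self) -> list:
        return [cid for ids in self.assignments.values() for cid in ids]

    def to_pairs(self) -> list:
        return [(case, ctrl) for case, ids in sorted(self.assignments.items()) for ctrl in ids]

    def to_json(self) -> str:
        return json.dumps(
            {
                "assignments": self.assignments,
                "unmatched_cases": self.unmatched_cases,
                "iterations_used": self.iterations_used,
                "bin_occupancy": {str(k): v for k, v in self.bin_occupancy.items()},
            }
        )


def build_frequency_table(cases: Sequence[Subject], spec: MatchSpec) -> dict:
    """Distribution of the matching characteristics among the cases.

    Returns a mapping (age_bin_index, sex) -> case count; counts sum to
    the number of cases.
    """
    table: dict = {}
    for s in cases:
        key = spec.stratum(s)
        table[key] = table.get(key, 0) + 1
    return table


def frequency_match(
    cases: Sequence[Subject],
    controls: Sequence[Subject],
    spec: MatchSpec,
    ratio: Union[float, str] = "max",
) -> MatchResult:
    """Assign controls to cases by stratum at the requested control:case ratio.

    ``ratio="max"`` consumes every available control in each stratum that
    contains cases (pool-maximal).  A numeric ratio targets
    ``round(ratio * n_cases)`` controls per stratum, relaxed to the
    available pool when short.  Controls are never reused; cases in a
    stratum with no controls at all are reported in ``unmatched_cases``.
    Deterministic given ``spec.seed``.
    """
    case_ids = {s.id for s in cases}
    if case_ids & {s.id for s in controls}:
        raise ValueError("case and control id spaces overlap")
    freq = build_frequency_table(cases, spec)
    pools: dict = {}
    for s in controls:
        pools.setdefault(spec.stratum(s), []).append(s.id)

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    assignments: dict = {s.id: [] for s in cases}
    unmatched: list = []
    occupancy: dict = {}
    iterations = 1

    # Deterministic stratum order: by deficit (shortfall first), then key.
    def deficit(key):
        avail = len(pools.get(key, []))
        want = avail if ratio == "max" else int(round(float(ratio) * freq[key]))
        return want - avail

    for key in sorted(freq, key=lambda k: (-deficit(k), k)):
        n_cases_s = freq[key]
        pool = pools.get(key, [])
        if ratio == "max":
            target = len(pool)
        else:
            target = int(round(float(ratio) * n_cases_s))
        take = min(target, len(pool))
        if target > len(pool):
            iterations += 1  # target relaxed for this stratum
        chosen = list(rng.choice(pool, size=take, replace=False)) if take else []
        stratum_cases = [s.id for s in cases if spec.stratum(s) == key]
        if not pool:
            unmatched.extend(stratum_cases)
        else:
            # Spread selected controls over the stratum's cases round-robin.
            for i, cid in enumerate(sorted(chosen)):
                assignments[stratum_cases[i % len(stratum_cases)]].append(cid)
        occupancy[key] = {"label": f"{spec.bin_label(key[0])}/{key[1]}",
                          "cases": n_cases_s, "controls": take, "pool": len(pool)}

    return MatchResult(
        assignments={k: v for k, v in assignments.items() if k not in unmatched},
        unmatched_cases=unmatched,
        iterations_used=iterations,
        bin_occupancy=occupancy,
    )


def match_balance(result: MatchResult, cases: Sequence[Subject], controls: Sequence[Subject]) -> dict:
    """Covariate balance: the full case series versus the matched controls.

    Age is compared by Welch t, sex by chi-square; an imbalance at
    p < 0.01 is flagged with a warning entry.  Comparing all cases (not
    only those with assigned controls) against the selected control set
    is what reveals a failed matching.
    """
    matched_ids = set(result.matched_control_ids)
    matched_controls = [s for s in controls if s.id in matched_ids]
    matched_cases = list(cases)
    if not matched_cases or not matched_controls:
        raise ValueError("no matched subjects to compare")

    def summarize(subs):
        ages = np.array([s.age_years for s in subs])
        nf = sum(1 for s in subs if s.sex == "female")
        return {"n": len(subs), "age_mean": float(ages.mean()),
                "age_sd": float(ages.std(ddof=1)) if len(subs) > 1 else math.nan,
                "n_female": nf, "prop_female": nf / len(subs)}

    ca, co = summarize(matched_cases), summarize(matched_controls)
    age_test = t_test_from_summary(ca["age_mean"], ca["age_sd"], ca["n"],
                                   co["age_mean"], co["age_sd"], co["n"], variant="welch")
    sex_table = ContingencyTable(
        cells=np.array([[ca["n_female"], co["n_female"]],
                        [ca["n"] - ca["n_female"], co["n"] - co["n_female"]]]),
        row_labels=("female", "male"), col_labels=("case", "control"))
    if ca["prop_female"] == co["prop_female"]:
        sex_test = TestResult(statistic=0.0, df=1.0, p_value=1.0, method="pearson-chisq",
                              note="identical proportions")
    else:
        sex_test = chisq_test(sex_table)
    report = {"cases": ca, "controls": co,
              "age_p": age_test.p_value, "sex_p": sex_test.p_value, "warnings": []}
    if sex_test.p_value < 0.01:
        report["warnings"].append("sex distributions differ at p < 0.01 despite matching")
    if age_test.p_value < 0.01:
        report["warnings"].append("age distributions differ at p < 0.01 despite matching")
    return report
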