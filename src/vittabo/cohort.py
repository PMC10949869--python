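"""Subject-level data model, cohort table I/O, and tabulation.

A cohort is a list of :class:`Subject` rows: vaccinated CVT cases and
unvaccinated pre-pandemic CVT controls, each carrying age at diagnosis,
sex, ABO phenotype, a VITT classification (cases only), the first-dose
vaccine, and optional binary thrombophilia covariate flags.

Tables are delimited text (UTF-8, comma by default) with a mandatory
header.  Phenotype/sex/group tokens are case-insensitive on read and
written in canonical form.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")
SEXES = ("female", "male")
PHENOTYPES = ("O", "A", "B", "AB")
VITT_CLASSES = ("Definite", "Probable", "Possible", "Unlikely")
VACCINES = ("ChAdOx1-S", "non-ChAdOx1-S")

#: Thrombophilia exclusion-criteria flags carried as 0/1 covariate columns.
COVARIATE_NAMES = (
    "lupus_anticoagulant",
    "antiphospholipid_antibodies",
    "protein_c_deficiency",
    "protein_s_deficiency",
    "antithrombin_deficiency",
    "fviii",
    "factor_v_leiden",
    "prothrombin_g20210a",
)

_REQUIRED_COLUMNS = ("id", "group", "age_years", "sex", "abo_phenotype", "vitt_class", "first_vaccine")


class CohortError(ValueError):
    """Raised for malformed cohort tables or invalid subject rows."""


@dataclass
class Subject:
    """One cohort row.

    ``vitt_class`` and ``first_vaccine`` are ``None`` for controls
    (not-applicable); ``abo_phenotype`` is ``None`` when blood type was
    not recorded.
    """

    id: str
    group: str
    age_years: float
    sex: str
    abo_phenotype: Optional[str] = None
    vitt_class: Optional[str] = None
    first_vaccine: Optional[str] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"unknown group token {self.group!r} for subject {self.id!r}")
        if self.sex not in SEXES:
            raise CohortError(f"unknown sex token {self.sex!r} for subject {self.id!r}")
        if self.abo_phenotype is not None and self.abo_phenotype not in PHENOTYPES:
            raise CohortError(f"unknown phenotype token {self.abo_phenotype!r} for subject {self.id!r}")
        if self.vitt_class is not None and self.vitt_class not in VITT_CLASSES:
            raise CohortError(f"unknown VITT class {self.vitt_class!r} for subject {self.id!r}")
        if self.first_vaccine is not None and self.first_vaccine not in VACCINES:
            raise CohortError(f"unknown vaccine token {self.first_vaccine!r} for subject {self.id!r}")
        if self.group == "case" and self.vitt_class is None:
            raise CohortError(f"case {self.id!r} lacks a VITT classification")
        if self.group == "control" and self.vitt_class is not None:
            raise CohortError(f"control {self.id!r} carries a VITT classification")
        if self.age_years < 0:
            raise CohortError(f"negative age for subject {self.id!r}")


@dataclass(frozen=True)
class PhenotypeCounts:
    """O/A/B/AB phenotype counts for one group -- the EM input."""

    nO: int
    nA: int
    nB: int
    nAB: int

    def __post_init__(self) -> None:
        for name in ("nO", "nA", "nB", "nAB"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.nO + self.nA + self.nB + self.nAB

    def as_array(self) -> np.ndarray:
        """Counts in canonical (O, A, B, AB) order."""
        return np.array([self.nO, self.nA, self.nB, self.nAB], dtype=float)

    def percentages(self) -> dict:
        if self.n == 0:
            raise ValueError("cannot compute percentages of an empty group")
        return {p: 100.0 * c / self.n for p, c in zip(PHENOTYPES, self.as_array())}


@dataclass(frozen=True)
class ContingencyTable:
    """r x c non-negative integer table with row/column labels."""

    cells: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=float)
        if cells.ndim != 2:
            raise ValueError("cells must be a 2-D matrix")
        if cells.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("cell dimensions do not match labels")
        if (cells < 0).any():
            raise ValueError("negative cell count")
        object.__setattr__(self, "cells", cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.row_labels), columns=list(self.col_labels))


def _parse_token(raw: str, canonical: Sequence[str], what: str, row: int):
    """Case-insensitive token lookup; empty string means missing."""
    token = raw.strip()
    if token == "":
        return None
    for c in canonical:
        if token.lower() == c.lower():
            return c
    raise CohortError(f"row {row}: unknown {what} token {token!r}")


def read_cohort(
    path,
    delimiter: str = ",",
    underage: str = "warn",
    covariate_names: Sequence[str] = COVARIATE_NAMES,
) -> list:
    """Read a delimited cohort table into validated :class:`Subject` rows.

    Parameters
    ----------
    path : path-like
        Delimited text file with a header naming at least the columns
        ``id, group, age_years, sex, abo_phenotype, vitt_class,
        first_vaccine``.  Covariate columns are read when present.
    delimiter : str
        Field separator (default comma).
    underage : {"warn", "error"}
        Policy for subjects younger than 18 (the inclusion criterion is
        age >= 18 at CVT diagnosis).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if underage not in ("warn", "error"):
        raise ValueError("underage must be 'warn' or 'error'")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"missing required columns: {missing}")
    present_covs = [c for c in covariate_names if c in df.columns]
    if df.empty:
        logger.warning("cohort file %s contains a header but no rows", path)
        return []

    subjects = []
    seen: set = set()
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, after the header line
        sid = row["id"].strip()
        if not sid:
            raise CohortError(f"row {rownum}: empty id")
        if sid in seen:
            raise CohortError(f"row {rownum}: duplicate id {sid!r}")
        seen.add(sid)
        group = _parse_token(row["group"], GROUPS, "group", rownum)
        if group is None:
            raise CohortError(f"row {rownum}: missing group")
        sex = _parse_token(row["sex"], SEXES, "sex", rownum)
        if sex is None:
            raise CohortError(f"row {rownum}: missing sex")
        try:
            age = float(row["age_years"])
        except ValueError:
            raise CohortError(f"row {rownum}: unparseable age {row['age_years']!r}") from None
        if age < 18:
            if underage == "error":
                raise CohortError(f"row {rownum}: age {age} below inclusion minimum 18")
            logger.warning("row %d: age %.1f below inclusion minimum 18", rownum, age)
        pheno = _parse_token(row["abo_phenotype"], PHENOTYPES, "phenotype", rownum)
        vitt = _parse_token(row["vitt_class"], VITT_CLASSES, "VITT class", rownum)
        vaccine = _parse_token(row["first_vaccine"], VACCINES, "vaccine", rownum)
        covs = {}
        for c in present_covs:
            raw = row[c].strip()
            if raw != "":
                covs[c] = int(raw)
        try:
            subjects.append(
                Subject(id=sid, group=group, age_years=age, sex=sex, abo_phenotype=pheno,
                        vitt_class=vitt, first_vaccine=vaccine, covariates=covs)
            )
        except CohortError as exc:
            raise CohortError(f"row {rownum}: {exc}") from None
    return subjects


def write_cohort(subjects: Iterable[Subject], path, delimiter: str = ",") -> None:
    """Write subjects to a delimited table readable by :func:`read_cohort`."""
    subjects = list(subjects)
    cov_names = sorted({k for s in subjects for k in s.covariates})
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "group": s.group,
            "age_years": s.age_years,
            "sex": s.sex,
            "abo_phenotype": s.abo_phenotype or "",
            "vitt_class": s.vitt_class or "",
            "first_vaccine": s.first_vaccine or "",
        }
        for c in cov_names:
            row[c] = s.covariates.get(c, 0)
        rows.append(row)
    cols = list(_REQUIRED_COLUMNS) + cov_names
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=delimiter, index=False)


def filter_vitt(
    subjects: Sequence[Subject],
    classes: Iterable[str],
    first_vaccine: Optional[str] = None,
    cases_only: bool = True,
) -> list:
    """Restrict cases to the given VITT classes (and optionally vaccine).

    With ``cases_only=True`` (default) controls pass through unchanged;
    otherwise the filter is applied to every subject.  Order-preserving
    and idempotent.
    """
    classes = set(classes)
    if not classes:
        raise ValueError("empty VITT class set")
    unknown = classes - set(VITT_CLASSES)
    if unknown:
        raise ValueError(f"unknown VITT classes: {sorted(unknown)}")

    def keep(s: Subject) -> bool:
        if cases_only and s.group == "control":
            return True
        if s.vitt_class not in classes:
            return False
        if first_vaccine is not None and s.first_vaccine != first_vaccine:
            return False
        return True

    return [s for s in subjects if keep(s)]


def tabulate_phenotypes(
    subjects: Sequence[Subject],
    by_group: bool = True,
    missing: str = "drop",
) -> dict:
    """Count O/A/B/AB phenotypes, by group or pooled.

    Parameters
    ----------
    missing : {"drop", "error"}
        Subjects with no recorded phenotype are dropped with a logged
        warning (default) or raise.

    Returns
    -------
    dict mapping group label (or ``"all"``) to :class:`PhenotypeCounts`.
    """
    if missing not in ("drop", "error"):
        raise ValueError("missing must be 'drop' or 'error'")
    kept = []
    n_missing = 0
    for s in subjects:
        if s.abo_phenotype is None:
            if missing == "error":
                raise CohortError(f"subject {s.id!r} has no recorded phenotype")
            n_missing += 1
            continue
        kept.append(s)
    if n_missing:
        logger.warning("dropped %d subjects with missing phenotype", n_missing)

    def counts(subs) -> PhenotypeCounts:
        tally = {p: 0 for p in PHENOTYPES}
        for s in subs:
            tally[s.abo_phenotype] += 1
        return PhenotypeCounts(tally["O"], tally["A"], tally["B"], tally["AB"])

    if not by_group:
        return {"all": counts(kept)}
    out = {}
    groups_present = {s.group for s in subjects}
    for g in GROUPS:
        if g not in groups_present:
            continue
        subs = [s for s in kept if s.group == g]
        if not subs:
            raise CohortError(f"group {g!r} has no subjects with a recorded phenotype")
        out[g] = counts(subs)
    return out


def make_contingency(
    counts_a: PhenotypeCounts,
    counts_b: PhenotypeCounts,
    levels: Sequence[str] = PHENOTYPES,
    col_labels: Sequence[str] = ("case", "control"),
) -> ContingencyTable:
    """Phenotype x group contingency table restricted to ``levels``.

    Rows follow canonical (O, A, B, AB) order regardless of the order
    levels are requested in.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("requested level set is empty")
    unknown = set(levels) - set(PHENOTYPES)
    if unknown:
        raise ValueError(f"unknown phenotype levels: {sorted(unknown)}")
    rows = [p for p in PHENOTYPES if p in levels]
    a = dict(zip(PHENOTYPES, counts_a.as_array()))
    b = dict(zip(PHENOTYPES, counts_b.as_array()))
    cells = np.array([[a[p], b[p]] for p in rows])
    return ContingencyTable(cells=cells, row_labels=tuple(rows), col_labels=tuple(col_labels))


def counts_to_tidy(counts_by_group: Mapping[str, PhenotypeCounts]) -> pd.DataFrame:
    """Tidy (group, phenotype, count, percent) frame for export."""
    rows = []
    for g, c in counts_by_group.items():
        pct = c.percentages()
        for p, v in zip(PHENOTYPES, c.as_array()):
            rows.append({"group": g, "phenotype": p, "count": int(v), "percent": pct[p]})
    return pd.DataFrame(rows)


def counts_to_json(counts_by_group: Mapping[str, PhenotypeCounts]) -> str:
    return json.dumps(
        {
            g: {"counts": dict(zip(PHENOTYPES, map(int, c.as_array()))), "percent": c.percentages()}
            for g, c in counts_by_group.items()
        },
        indent=2,
    )
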