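"""End-to-end orchestration: ingest -> filter -> (match) -> describe ->
contingency -> logistic -> allele EM -> permutation -> report.

The report mirrors the shape of a standard case-control write-up: a
cohort characteristics table, a phenotype distribution table with
percentages, odds ratios, test results, per-group allele frequencies
with bootstrap CIs, and the permutation contrasts -- every statistic
tagged with its method and settings, and every random stage with its
seed, so a rerun with the same configuration reproduces the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from vittabo.alleles import ALLELES, bootstrap_allele_ci, em_abo, permutation_allele_diff
from vittabo.cohort import (
    PHENOTYPES,
    ContingencyTable,
    make_contingency,
    read_cohort,
    tabulate_phenotypes,
)
from vittabo.cohort import filter_vitt as _filter_vitt
from vittabo.matching import MatchSpec, frequency_match, match_balance
from vittabo.simulate import reference_cohort
from vittabo.stats import chisq_test, fisher_exact_2x2, logistic_fit, odds_ratio_2x2, t_test_from_summary

logger = logging.getLogger(__name__)

try:
    from importlib.metadata import version as _pkg_version
    _version = _pkg_version("vittabo")
except Exception:  # pragma: no cover
    _version = "0.1.0"

SIGNIFICANCE_THRESHOLD = 0.01  # per-comparison; no family-wise correction


class PipelineError(RuntimeError):
    """Stage-named pipeline failure carrying the partial report."""

    def __init__(self, stage: str, message: str, partial_report: dict):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.partial_report = partial_report


@dataclass
class PipelineConfig:
    """Analysis configuration; ``cohort=None`` uses the packaged reference cohort."""

    cohort: Optional[str] = None
    delimiter: str = ","
    vitt_classes: tuple = ("Definite", "Probable")
    first_vaccine: Optional[str] = "ChAdOx1-S"
    match_spec: Optional[MatchSpec] = None
    seed: int = 0
    n_boot: int = 10000
    n_perm: int = 9999
    ci_level: float = 0.95


@dataclass
class AnalysisReport:
    config: dict
    cohort_summary: dict
    phenotype_table: dict
    odds_ratio: dict
    tests: dict
    allele_estimates: dict
    permutation: dict
    matching: Optional[dict] = None
    version: str = _version

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.match_spec is not None:
        d["match_spec"] = dataclasses.asdict(config.match_spec)
    return d


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis and return a structured report.

    Reruns with an identical configuration are identical: deterministic
    stages are bit-reproducible and stochastic stages (matching,
    bootstrap, permutation) are seeded from ``config.seed``.
    """
    partial: dict = {"config": _config_dict(config)}
    stage = "ingest"
    try:
        subjects = read_cohort(config.cohort, delimiter=config.delimiter) \
            if config.cohort else reference_cohort()
        if not subjects:
            raise ValueError("cohort is empty")
        logger.info("ingested %d subjects (seed=%d, version=%s)", len(subjects), config.seed, _version)

        stage = "filter"
        subjects = _filter_vitt(subjects, config.vitt_classes, first_vaccine=config.first_vaccine)
        cases = [s for s in subjects if s.group == "case"]
        controls = [s for s in subjects if s.group == "control"]
        if not cases or not controls:
            raise ValueError("need both cases and controls after filtering")

        stage = "match"
        matching_report = None
        if config.match_spec is not None:
            mres = frequency_match(cases, controls, config.match_spec)
            keep = set(mres.matched_control_ids)
            controls = [s for s in controls if s.id in keep]
            subjects = cases + controls
            matching_report = {
                "iterations_used": mres.iterations_used,
                "n_matched_controls": len(controls),
                "unmatched_cases": mres.unmatched_cases,
                "balance": match_balance(mres, cases, controls),
                "seed": config.match_spec.seed,
            }
        partial["matching"] = matching_report

        stage = "describe"
        def describe(subs):
            ages = np.array([s.age_years for s in subs])
            nf = sum(1 for s in subs if s.sex == "female")
            return {"n": len(subs), "age_mean": float(ages.mean()),
                    "age_sd": float(ages.std(ddof=1)), "n_female": nf,
                    "pct_female": round(100 * nf / len(subs), 1)}
        ca, co = describe(cases), describe(controls)
        age_test = t_test_from_summary(ca["age_mean"], ca["age_sd"], ca["n"],
                                       co["age_mean"], co["age_sd"], co["n"], variant="welch")
        cohort_summary = {"cases": ca, "controls": co,
                          "age_test": dataclasses.asdict(age_test)}
        partial["cohort_summary"] = cohort_summary

        stage = "contingency"
        counts = tabulate_phenotypes(subjects)
        pheno_table = {
            g: {"counts": dict(zip(PHENOTYPES, map(int, c.as_array()))),
                "percent": {k: round(v, 1) for k, v in c.percentages().items()},
                "n": c.n}
            for g, c in counts.items()
        }
        full_table = make_contingency(counts["case"], counts["control"])
        overall = chisq_test(full_table)
        expected = np.outer(full_table.cells.sum(axis=1), full_table.cells.sum(axis=0)) / full_table.cells.sum()
        if (expected < 5).any():
            logger.info("expected cell below 5 in the 4x2 table; chi-square may be fragile")
        oa_table = make_contingency(counts["case"], counts["control"], levels=("O", "A"))
        # Fisher auto-selected for the 2x2 when an expected cell is small.
        exp_oa = np.outer(oa_table.cells.sum(axis=1), oa_table.cells.sum(axis=0)) / oa_table.cells.sum()
        oa_test = fisher_exact_2x2(oa_table) if (exp_oa < 5).any() else chisq_test(oa_table)
        or_result = odds_ratio_2x2(oa_table, level=config.ci_level)
        partial["phenotype_table"] = pheno_table

        stage = "logistic"
        # Univariate model on the O-vs-A subset: outcome = case membership,
        # predictor = indicator of blood group O.
        oa_subjects = [s for s in subjects if s.abo_phenotype in ("O", "A")]
        y = np.array([1 if s.group == "case" else 0 for s in oa_subjects])
        x = np.array([[1.0 if s.abo_phenotype == "O" else 0.0] for s in oa_subjects])
        fit = logistic_fit(x, y, names=["blood_group_O"])
        logistic_report = {
            "coefficients": fit.coefficients, "standard_errors": fit.standard_errors,
            "or_from_slope": float(np.exp(fit.coefficients["blood_group_O"])) if fit.coefficients else None,
            "aic": fit.aic, "converged": fit.converged,
            "separation_detected": fit.separation_detected,
        }

        stage = "allele-em"
        rng = np.random.default_rng(config.seed)
        allele_estimates: dict = {}
        for g in ("case", "control"):
            res = em_abo(counts[g])
            entry = {"n": counts[g].n, "n_iter": res.n_iter, "converged": res.converged,
                     "loglik": res.loglik, "frequencies": {}, "ci_method": "percentile-bootstrap"}
            for allele in ALLELES:
                ci = bootstrap_allele_ci(counts[g], allele, n_boot=config.n_boot,
                                         level=config.ci_level,
                                         seed=int(rng.integers(2**31 - 1)))
                entry["frequencies"][allele] = {
                    "estimate": ci.point,
                    "percent": round(100 * ci.point),
                    "percent_1dp": round(100 * ci.point, 1),
                    "ci_lower": ci.lower, "ci_upper": ci.upper,
                    "level": ci.level, "n_boot": ci.n_boot, "seed": ci.seed,
                }
            allele_estimates[g] = entry
        partial["allele_estimates"] = allele_estimates

        stage = "permutation"
        case_phenos = [s.abo_phenotype for s in cases if s.abo_phenotype]
        ctrl_phenos = [s.abo_phenotype for s in controls if s.abo_phenotype]
        permutation = {}
        for allele in ALLELES:
            res = permutation_allele_diff(case_phenos, ctrl_phenos, allele,
                                          n_perm=config.n_perm,
                                          seed=int(rng.integers(2**31 - 1)))
            permutation[allele] = dataclasses.asdict(res)
            permutation[allele]["significant"] = res.p_value < SIGNIFICANCE_THRESHOLD

        stage = "report"
        return AnalysisReport(
            config=_config_dict(config),
            cohort_summary=cohort_summary,
            phenotype_table=pheno_table,
            odds_ratio={**dataclasses.asdict(or_result), "exposure": "O vs A",
                        "significant": oa_test.p_value < SIGNIFICANCE_THRESHOLD},
            tests={
                "blood_type_overall": dataclasses.asdict(overall),
                "o_vs_a": dataclasses.asdict(oa_test),
                "age": dataclasses.asdict(age_test),
                "logistic_o_vs_a": logistic_report,
            },
            allele_estimates=allele_estimates,
            permutation=permutation,
            matching=matching_report,
        )
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("pipeline stage %s failed: %s; partial report follows\n%s",
                     stage, exc, json.dumps(partial, default=str, indent=2))
        raise PipelineError(stage, str(exc), partial) from exc


def _markdown_table(header, rows) -> str:
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    lines += ["| " + " | ".join(str(c) for c in r) + " |" for r in rows]
    return "\n".join(lines)


def render_report(report: AnalysisReport, fmt: str = "json") -> str:
    """Render a report as lossless JSON, markdown tables, or tidy TSV."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, default=str)
    if fmt == "markdown":
        d = report.to_dict()
        out = ["# Analysis report", ""]
        cs = d["cohort_summary"]
        out.append("## Cohort characteristics")
        out.append(_markdown_table(
            ["", f"Cases (n={cs['cases']['n']})", f"Controls (n={cs['controls']['n']})", "p"],
            [["Age, mean (SD)",
              f"{cs['cases']['age_mean']:.1f} ({cs['cases']['age_sd']:.1f})",
              f"{cs['controls']['age_mean']:.1f} ({cs['controls']['age_sd']:.1f})",
              f"{cs['age_test']['p_value']:.2f}"],
             ["Women, n (%)",
              f"{cs['cases']['n_female']} ({cs['cases']['pct_female']})",
              f"{cs['controls']['n_female']} ({cs['controls']['pct_female']})", ""]]))
        out.append("")
        out.append("## Blood type distribution")
        pt = d["phenotype_table"]
        rows = []
        for p in PHENOTYPES:
            rows.append([p,
                         f"{pt['case']['counts'][p]} ({pt['case']['percent'][p]})",
                         f"{pt['control']['counts'][p]} ({pt['control']['percent'][p]})"])
        out.append(_markdown_table(["Blood type", "Cases n (%)", "Controls n (%)"], rows))
        out.append("")
        orr = d["odds_ratio"]
        out.append(f"Odds ratio ({orr['exposure']}): {orr['or_point']:.2f} "
                   f"({orr['level']:.0%} CI {orr['ci_lower']:.2f}-{orr['ci_upper']:.2f})")
        out.append("")
        out.append("## Allele frequencies (EM gene counting, bootstrap CI)")
        rows = []
        for g, entry in d["allele_estimates"].items():
            for allele, v in entry["frequencies"].items():
                rows.append([g, allele, f"{v['percent']}%",
                             f"{100*v['ci_lower']:.0f}-{100*v['ci_upper']:.0f}"])
        out.append(_markdown_table(["Group", "Allele", "Estimate", f"CI"], rows))
        return "\n".join(out)
    if fmt == "tsv":
        rows = [("statistic", "value", "detail")]
        d = report.to_dict()
        rows.append(("n_cases", d["cohort_summary"]["cases"]["n"], ""))
        rows.append(("n_controls", d["cohort_summary"]["controls"]["n"], ""))
        for g, entry in d["phenotype_table"].items():
            for p in PHENOTYPES:
                rows.append((f"pct_{p}_{g}", entry["percent"][p], f"count={entry['counts'][p]}"))
        orr = d["odds_ratio"]
        rows.append(("odds_ratio_O_vs_A", orr["or_point"],
                     f"CI {orr['ci_lower']:.4f}-{orr['ci_upper']:.4f}"))
        for name, t in d["tests"].items():
            val = t.get("p_value") if isinstance(t, dict) else None
            if val is not None:
                rows.append((f"p_{name}", val, t.get("method", "")))
        for g, entry in d["allele_estimates"].items():
            for allele, v in entry["frequencies"].items():
                rows.append((f"allele_{allele}_{g}", v["estimate"],
                             f"CI {v['ci_lower']:.4f}-{v['ci_upper']:.4f} seed={v['seed']}"))
        for allele, v in d["permutation"].items():
            rows.append((f"perm_p_{allele}", v["p_value"],
                         f"diff={v['observed_diff']:.4f} n_perm={v['n_perm']} seed={v['seed']}"))
        return "\n".join("\t".join(str(c) for c in r) for r in rows)
    raise ValueError(f"unknown format {fmt!r}")
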