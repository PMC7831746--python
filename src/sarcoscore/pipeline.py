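"""End-to-end study workflow: classify, QC, associate, model, score, report.

Stage order mirrors the study's analysis plan:

1. EWGSOP phenotype classification (only when the table carries no status);
2. per-group Hardy-Weinberg QC — a SNP whose *controls* deviate at the QC
   alpha is excluded from every downstream table (the CX3CR1-style drop);
   case-group deviation is reported but does not exclude;
3. genotype (2x3), allelic, dominant and recessive association for every
   retained SNP, with Woolf-CI odds ratios;
4. unadjusted and covariate-adjusted logistic models (dominant, recessive);
5. risk-allele orientation, the additive risk score, ROC/AUC and the Youden
   cutoff over the configured score SNPs;
6. a machine-readable JSON summary plus fixed-format TSV tables.

Outputs are deterministic: same config + inputs => byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .association import (
    AssociationResult,
    allele_table,
    chisq_test,
    genotype_table,
    model_table,
    odds_ratio_woolf,
)
from .cohort_io import (
    CohortRecord,
    SnpPanelEntry,
    call_rate_summary,
    genotype_counts,
)
from .grs import auc, orient_risk_alleles, roc_curve, score_cohort, youden_cutoff
from .hwe import hwe_chisq
from .logistic import DesignSpec, SeparationError, fit_model
from .phenotype import DEFAULT_CUTOFFS, CutoffSet, classify_cohort

logger = logging.getLogger("sarcoscore")

__all__ = ["RunConfig", "PipelineError", "run_study_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: Path
    alpha: float = 0.05
    hwe_alpha: float = 0.05
    covariates: tuple[str, ...] = ("age", "sex", "physical_activity")
    score_snps: Sequence[str] | None = None  # default: all retained oriented SNPs
    cutoffs: CutoffSet = field(default_factory=lambda: DEFAULT_CUTOFFS)
    reclassify: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1 or not 0 < self.hwe_alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _assoc_row(snp_id: str, res: AssociationResult, table) -> dict:
    return {
        "snp": snp_id, "model": res.model,
        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
        "OR": f"{res.or_:.3f}", "CI_low": f"{res.ci_low:.3f}",
        "CI_high": f"{res.ci_high:.3f}", "chi2": f"{res.chi2:.3f}",
        "df": res.df, "p": _fmt_p(res.p), "flags": ";".join(res.flags),
    }


def _write_tsv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("", encoding="utf-8")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(r[c]) for c in cols) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_study_pipeline(
    records: list[CohortRecord],
    panel: Sequence[SnpPanelEntry],
    config: RunConfig,
) -> dict:
    """Run the full workflow; writes TSV/JSON outputs and returns the summary."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "alpha": config.alpha}
    written: list[Path] = []

    try:
        # ---- stage 1: phenotype classification
        n_unclassified = sum(r.status == "unclassified" for r in records)
        if n_unclassified or config.reclassify:
            logger.info("classifying %d unlabelled participants", n_unclassified)
            records = classify_cohort(records, config.cutoffs, overwrite=config.reclassify)
        n_cases = sum(r.status == "sarcopenic" for r in records)
        n_controls = sum(r.status == "non_sarcopenic" for r in records)
        if n_cases == 0 or n_controls == 0:
            raise PipelineError("phenotype", "need both cases and controls")
        summary["n_cases"] = n_cases
        summary["n_controls"] = n_controls
        summary["prevalence_percent"] = round(100.0 * n_cases / (n_cases + n_controls), 1)
        summary["call_rates"] = call_rate_summary(records, panel).to_dict("records")

        # ---- stage 2: HWE QC per group
        hwe_rows, retained = [], []
        for entry in panel:
            grouped = genotype_counts(records, entry.snp_id, entry, by_status=True)
            excluded = False
            for group, counts in grouped.items():
                try:
                    res = hwe_chisq(counts)
                except ValueError as exc:
                    logger.warning("HWE skipped for %s/%s: %s", entry.snp_id, group, exc)
                    continue
                deviates = res.p < config.hwe_alpha
                if deviates and group == "non_sarcopenic":
                    excluded = True
                hwe_rows.append({
                    "snp": entry.snp_id, "group": group,
                    "hom_risk": counts.n_hom_risk, "het": counts.n_het,
                    "hom_other": counts.n_hom_other,
                    "chi2": f"{res.chi2:.3f}", "p": _fmt_p(res.p),
                    "flag": "deviates" if deviates else "",
                })
            if excluded:
                logger.info("excluding %s: control group deviates from HWE", entry.snp_id)
            else:
                retained.append(entry)
        excluded_ids = [e.snp_id for e in panel if e not in retained]
        summary["hwe_excluded_snps"] = excluded_ids
        path = out / "hwe.tsv"
        _write_tsv(path, hwe_rows)
        written.append(path)
        if not retained:
            raise PipelineError("hwe", "all SNPs excluded by HWE QC")

        # ---- stage 3: risk-allele orientation on retained SNPs
        oriented, allelic_ors = orient_risk_alleles(records, retained)
        summary["risk_alleles"] = {
            e.snp_id: e.risk_allele for e in oriented if e.risk_allele
        }

        # ---- stage 4: contingency-table association
        assoc_rows, assoc_summary = [], {}
        for entry in oriented:
            grouped = genotype_counts(records, entry.snp_id, entry, by_status=True)
            cases, controls = grouped["sarcopenic"], grouped["non_sarcopenic"]
            chi2_g, p_g, df_g, _ = chisq_test(genotype_table(cases, controls))
            assoc_rows.append({
                "snp": entry.snp_id, "model": "genotypic",
                "a": "", "b": "", "c": "", "d": "",
                "OR": "", "CI_low": "", "CI_high": "",
                "chi2": f"{chi2_g:.3f}", "df": df_g, "p": _fmt_p(p_g), "flags": "",
            })
            per_snp = {"genotypic": {"chi2": chi2_g, "df": df_g, "p": p_g}}
            tables = {"allelic": allele_table(cases, controls)}
            for model in ("dominant", "recessive"):
                tables[model] = model_table(cases, controls, model)  # type: ignore[arg-type]
            for model, table in tables.items():
                res = odds_ratio_woolf(table, model=model)
                assoc_rows.append(_assoc_row(entry.snp_id, res, table))
                per_snp[model] = {
                    "or": res.or_, "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "chi2": res.chi2, "p": res.p,
                }
            assoc_summary[entry.snp_id] = per_snp
        summary["association"] = assoc_summary
        path = out / "association.tsv"
        _write_tsv(path, assoc_rows)
        written.append(path)

        # ---- stage 5: logistic models (unadjusted + adjusted)
        logistic_rows, logistic_summary = [], {}
        for entry in oriented:
            per_snp = {}
            for coding in ("dominant", "recessive"):
                for covariates in ((), config.covariates):
                    label = "adjusted" if covariates else "unadjusted"
                    design = DesignSpec(entry.snp_id, coding, covariates)  # type: ignore[arg-type]
                    try:
                        fit = fit_model(records, design, oriented)
                    except (SeparationError, ValueError) as exc:
                        logger.warning("logistic %s %s %s failed: %s",
                                       entry.snp_id, coding, label, exc)
                        continue
                    i = fit.term(f"{entry.snp_id}_{coding}")
                    logistic_rows.append({
                        "snp": entry.snp_id, "model": coding, "adjusted": label == "adjusted",
                        "OR": f"{fit.or_[i]:.3f}", "CI_low": f"{fit.ci_low[i]:.3f}",
                        "CI_high": f"{fit.ci_high[i]:.3f}", "p": _fmt_p(fit.p[i]),
                        "nagelkerke_r2": f"{fit.nagelkerke_r2:.3f}", "n_used": fit.n_used,
                    })
                    per_snp[f"{coding}_{label}"] = {
                        "or": float(fit.or_[i]), "ci_low": float(fit.ci_low[i]),
                        "ci_high": float(fit.ci_high[i]), "p": float(fit.p[i]),
                        "nagelkerke_r2": fit.nagelkerke_r2, "n_used": fit.n_used,
                    }
            logistic_summary[entry.snp_id] = per_snp
        summary["logistic"] = logistic_summary
        path = out / "logistic.tsv"
        _write_tsv(path, logistic_rows)
        written.append(path)

        # ---- stage 6: genetic risk score + ROC
        score_ids = list(config.score_snps or [e.snp_id for e in oriented])
        score_ids = [s for s in score_ids if s not in excluded_ids]
        scores, excluded_samples = score_cohort(records, oriented, score_ids)
        by_sample = {s.sample_id: s for s in scores}
        labelled = [
            (s.scaled, 1 if r.status == "sarcopenic" else 0)
            for r in records
            if (s := by_sample.get(r.sample_id)) is not None
            and r.status in ("sarcopenic", "non_sarcopenic")
        ]
        values = [v for v, _ in labelled]
        labels = [y for _, y in labelled]
        roc = roc_curve(values, labels)
        auc_res = auc(values, labels)
        cut = youden_cutoff(roc)
        case_scores = [v for v, y in labelled if y == 1]
        control_scores = [v for v, y in labelled if y == 0]
        above = lambda xs: sum(x >= cut.threshold for x in xs) / len(xs)  # noqa: E731
        summary["grs"] = {
            "snps": score_ids,
            "n_scored": len(scores),
            "n_excluded_missing": len(excluded_samples),
            "auc": auc_res.auc, "auc_ci": [auc_res.ci_low, auc_res.ci_high],
            "cutoff": cut.threshold, "youden_j": cut.youden_j,
            "sensitivity": cut.sensitivity, "specificity": cut.specificity,
            "case_above_cutoff": above(case_scores),
            "control_above_cutoff": above(control_scores),
        }
        path = out / "grs_scores.tsv"
        _write_tsv(path, [
            {"sample_id": s.sample_id, "raw": s.raw, "scaled": f"{s.scaled:.1f}"}
            for s in scores
        ])
        written.append(path)
        path = out / "roc.tsv"
        _write_tsv(path, [
            {"threshold": f"{t:.4f}", "sensitivity": f"{se:.4f}",
             "specificity": f"{sp:.4f}"}
            for t, se, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity)
        ])
        written.append(path)

        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                                encoding="utf-8")
        return summary

    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # tag unexpected failures with a stage marker
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("internal", str(exc)) from exc
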