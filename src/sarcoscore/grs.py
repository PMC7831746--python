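"""Additive genetic risk score with ROC analysis and Youden cutoff.

The Total Sarcopenia Genetic Risk Score is unweighted: each of the K score
SNPs contributes its risk-allele dosage (0, 1 or 2) and the sum is rescaled
by 100 / (2K) onto a 0-100 percent scale; with the study's three score SNPs
this is the 100/6 formula, so 100% means homozygous for the risk allele at
every score SNP.  Scores therefore live on the lattice {0, 100/(2K), ...,
100}.

ROC analysis uses the "score >= threshold predicts case" rule, candidate
thresholds at midpoints between consecutive distinct observed scores plus
sentinels beyond the extremes, AUC by the Mann-Whitney rank formulation
(ties counted 1/2) with a Hanley-McNeil normal-approximation CI, and the
Youden index J = sensitivity + specificity - 1 to select the operating
cutoff; J ties break toward higher sensitivity, then lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .association import allele_table, odds_ratio_woolf
from .cohort_io import (
    CohortRecord,
    GenotypeCall,
    SnpPanelEntry,
    genotype_counts,
    genotype_dosage,
)

__all__ = [
    "GrsResult",
    "RocCurve",
    "CutoffResult",
    "AucResult",
    "sgs",
    "score_cohort",
    "roc_curve",
    "auc",
    "youden_cutoff",
    "orient_risk_alleles",
]


@dataclass(frozen=True)
class GrsResult:
    sample_id: str
    raw: int
    scaled: float
    n_snps: int


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points, ordered by increasing threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    def points(self) -> np.ndarray:
        """(fpr, sensitivity) pairs, ordered for trapezoidal integration."""
        order = np.argsort(self.fpr, kind="stable")
        return np.column_stack([self.fpr[order], self.sensitivity[order]])


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str = "mann-whitney / hanley-mcneil"


def sgs(scores: Sequence[int]) -> float:
    """Scale per-SNP dosages (each 0/1/2) to the 0-100 percent score."""
    k = len(scores)
    if k == 0:
        raise ValueError("no genotype scores supplied")
    for s in scores:
        if s not in (0, 1, 2):
            raise ValueError(f"genotype score must be 0, 1 or 2, got {s!r}")
    return 100.0 / (2 * k) * sum(scores)


def score_cohort(
    records: Sequence[CohortRecord],
    panel: Sequence[SnpPanelEntry],
    snp_ids: Sequence[str],
) -> tuple[list[GrsResult], dict[str, str]]:
    """Per-sample risk scores over ``snp_ids``; strict missingness.

    A sample missing any of the K genotypes is excluded; the second return
    value maps excluded sample ids to the reason.
    """
    by_id = {e.snp_id: e for e in panel}
    entries = []
    for snp_id in snp_ids:
        if snp_id not in by_id:
            raise ValueError(f"score SNP {snp_id!r} not in panel")
        if by_id[snp_id].risk_allele is None:
            raise ValueError(
                f"{snp_id}: risk allele undetermined; run orient_risk_alleles first"
            )
        entries.append(by_id[snp_id])

    results: list[GrsResult] = []
    excluded: dict[str, str] = {}
    for record in records:
        doses = []
        missing_at = None
        for entry in entries:
            call = record.genotypes.get(entry.snp_id, GenotypeCall.missing())
            dose = genotype_dosage(call, entry.risk_allele)
            if dose is None:
                missing_at = entry.snp_id
                break
            doses.append(dose)
        if missing_at is not None:
            excluded[record.sample_id] = f"missing genotype at {missing_at}"
            continue
        results.append(
            GrsResult(
                sample_id=record.sample_id,
                raw=sum(doses),
                scaled=sgs(doses),
                n_snps=len(entries),
            )
        )
    return results, excluded


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("ROC analysis needs both classes present")


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve with midpoint candidate thresholds and sentinels.

    Thresholds are the midpoints between consecutive distinct observed
    scores, plus one sentinel below the minimum (everything predicted
    positive: sensitivity 1, specificity 0) and one above the maximum.
    Prediction rule: score >= threshold => predicted case.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    _check_two_classes(y)
    distinct = np.unique(s)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    thresholds = np.concatenate(
        [[distinct[0] - span], midpoints, [distinct[-1] + span]]
    )
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    sens = np.array([(s[y == 1] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(s[y == 0] < t).sum() / n_neg for t in thresholds])
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def auc(scores: Sequence[float], labels: Sequence[int]) -> AucResult:
    """AUC by the rank (Mann-Whitney) formulation, ties counted 1/2.

    The confidence interval is the Hanley-McNeil normal approximation, with
    the exponential-distribution moment formulas for the variance, clipped
    to [0, 1].
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    _check_two_classes(y)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    ranks = stats.rankdata(s)
    a = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return AucResult(
        auc=float(a),
        ci_low=float(max(0.0, a - half)),
        ci_high=float(min(1.0, a + half)),
    )


def youden_cutoff(roc: RocCurve) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties break toward higher sensitivity (the score is framed as a
    screening instrument), then toward the lower threshold.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, len(j)):
        if (j[i], roc.sensitivity[i], -roc.thresholds[i]) > (
            j[best], roc.sensitivity[best], -roc.thresholds[best]
        ):
            best = i
    return CutoffResult(
        threshold=float(roc.thresholds[best]),
        youden_j=float(j[best]),
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
    )


def orient_risk_alleles(
    records: Sequence[CohortRecord],
    panel: Sequence[SnpPanelEntry],
    snp_ids: Sequence[str] | None = None,
) -> tuple[list[SnpPanelEntry], dict[str, float]]:
    """Set each SNP's risk allele to the case-enriched allele.

    The risk allele is the one with allelic odds ratio > 1 (cases vs
    controls); an OR of exactly 1 is ambiguous and raises.  Returns the
    re-oriented panel and the allelic OR recorded for each SNP (oriented to
    the chosen risk allele).
    """
    import dataclasses

    chosen_ids = set(snp_ids if snp_ids is not None else [e.snp_id for e in panel])
    out: list[SnpPanelEntry] = []
    ors: dict[str, float] = {}
    for entry in panel:
        if entry.snp_id not in chosen_ids:
            out.append(entry)
            continue
        grouped = genotype_counts(records, entry.snp_id, entry, by_status=True)
        cases, controls = grouped["sarcopenic"], grouped["non_sarcopenic"]
        table = allele_table(cases, controls)
        result = odds_ratio_woolf(table)
        reference = entry.risk_allele or entry.allele_pair[0]
        if result.or_ == 1.0:
            raise ValueError(
                f"{entry.snp_id}: allelic OR exactly 1; orient manually"
            )
        if result.or_ > 1.0:
            risk = reference
            ors[entry.snp_id] = result.or_
        else:
            a, b = entry.allele_pair
            risk = b if reference == a else a
            ors[entry.snp_id] = 1.0 / result.or_
        out.append(dataclasses.replace(entry, risk_allele=risk))
    return out, ors
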