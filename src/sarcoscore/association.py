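"""Contingency-table association statistics for case-control SNP data.

Codings of a biallelic SNP against binary case status:

* genotypic — the full 2x3 genotype table, Pearson chi-square with 2 df;
* allelic — each participant contributes two alleles to a 2x2 table;
* dominant — risk-allele carriers (het + hom) vs non-carriers;
* recessive — risk-allele homozygotes vs the rest.

Odds ratios come with Woolf (log-scale normal) 95% confidence intervals.
No continuity correction is applied anywhere and no multiple-testing
adjustment is made by default, matching the single-panel candidate-gene
setting.  ``counts_from_freq`` reconstructs integer counts from published
percentage frequencies, which is how the desk-scale analyses rebuild the
study's allele tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .cohort_io import GenotypeCounts

__all__ = [
    "Table2x2",
    "AssociationResult",
    "allele_table",
    "model_table",
    "genotype_table",
    "chisq_test",
    "odds_ratio_woolf",
    "counts_from_freq",
    "anova_tukey",
    "Z_95",
]

Z_95 = stats.norm.ppf(0.975)  # 1.959964...

Model = Literal["genotypic", "allelic", "dominant", "recessive"]


@dataclass(frozen=True)
class Table2x2:
    """Case/control by exposed/unexposed counts (a, b = cases; c, d = controls)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped_groups(self) -> "Table2x2":
        return Table2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssociationResult:
    model: str
    or_: float
    ci_low: float
    ci_high: float
    chi2: float
    df: int
    p: float
    n_effective: int
    flags: tuple[str, ...] = ()


def allele_table(cases: GenotypeCounts, controls: GenotypeCounts) -> Table2x2:
    """2x2 allele table; each genotype contributes two alleles."""
    return Table2x2(
        a=cases.n_risk_alleles,
        b=2 * cases.n - cases.n_risk_alleles,
        c=controls.n_risk_alleles,
        d=2 * controls.n - controls.n_risk_alleles,
    )


def model_table(
    cases: GenotypeCounts,
    controls: GenotypeCounts,
    model: Literal["dominant", "recessive"],
) -> Table2x2:
    """Collapse genotype counts to carriers (dominant) or homozygotes (recessive)."""
    if model == "dominant":
        exposed = lambda g: g.n_hom_risk + g.n_het  # noqa: E731
    elif model == "recessive":
        exposed = lambda g: g.n_hom_risk  # noqa: E731
    else:
        raise ValueError(f"unknown model {model!r}")
    return Table2x2(
        a=exposed(cases),
        b=cases.n - exposed(cases),
        c=exposed(controls),
        d=controls.n - exposed(controls),
    )


def genotype_table(cases: GenotypeCounts, controls: GenotypeCounts) -> np.ndarray:
    """Full 2x3 genotype-by-group table (rows cases/controls)."""
    return np.array(
        [
            [cases.n_hom_risk, cases.n_het, cases.n_hom_other],
            [controls.n_hom_risk, controls.n_het, controls.n_hom_other],
        ],
        dtype=float,
    )


def chisq_test(table: Table2x2 | np.ndarray) -> tuple[float, float, int, bool]:
    """Pearson chi-square without continuity correction.

    Returns ``(chi2, p, df, small_expected)`` where ``small_expected`` warns
    that some expected count is below 5.  A zero row or column margin is an
    error (the test is undefined).
    """
    obs = table.as_array() if isinstance(table, Table2x2) else np.asarray(table, float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square test undefined")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p), int(df), bool((expected < 5).any())


def odds_ratio_woolf(table: Table2x2, model: str = "allelic") -> AssociationResult:
    """Cross-product odds ratio with Woolf 95% CI.

    OR = ad/bc; CI = exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)).  Any zero
    cell triggers the Haldane-Anscombe correction (+0.5 to all four cells),
    reported via the ``haldane_anscombe`` flag; two zero cells on a diagonal
    leave the OR undefined and raise.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    flags: list[str] = []
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise ValueError("OR undefined: both cells of a diagonal are zero")
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        flags.append("haldane_anscombe")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(or_) - Z_95 * se)
    ci_high = math.exp(math.log(or_) + Z_95 * se)
    chi2, p, df, small = chisq_test(table)
    if small:
        flags.append("small_expected_count")
    return AssociationResult(
        model=model, or_=float(or_), ci_low=ci_low, ci_high=ci_high,
        chi2=chi2, df=df, p=p, n_effective=table.total, flags=tuple(flags),
    )


def counts_from_freq(freq_percent: float, n_samples: int, *, per_allele: bool) -> int:
    """Reconstruct an integer count from a printed percentage frequency.

    The denominator is ``2 * n_samples`` for allele frequencies and
    ``n_samples`` for genotype frequencies; rounding is half away from zero,
    which reproduces all published allele counts of the study panel.
    """
    if not 0 <= freq_percent <= 100:
        raise ValueError("frequency must be within [0, 100] percent")
    denominator = 2 * n_samples if per_allele else n_samples
    value = freq_percent / 100.0 * denominator
    return int(math.floor(value + 0.5))


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    group_means: dict[str, float]
    pairwise: list[tuple[str, str, float, float]]  # (g1, g2, mean diff, adj p)
    dropped: tuple[str, ...] = ()


def anova_tukey(groups: dict[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post hoc comparisons.

    Used for quantitative muscle traits across genotypes (sexes are analysed
    separately by the caller).  Groups with fewer than two values are dropped
    with a record of the fact; fewer than two usable groups is an error.
    """
    usable = {k: np.asarray(v, float) for k, v in groups.items() if len(v) >= 2}
    dropped = tuple(sorted(set(groups) - set(usable)))
    if len(usable) < 2:
        raise ValueError("ANOVA needs at least two groups with >= 2 values")
    names = sorted(usable)
    samples = [usable[name] for name in names]
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    if ss_between < 1e-12:  # identical group means: no effect by definition
        f, p = 0.0, 1.0
        pvalues = np.ones((len(names), len(names)))
    else:
        f, p = stats.f_oneway(*samples)
        pvalues = stats.tukey_hsd(*samples).pvalue
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = float(samples[i].mean() - samples[j].mean())
            pairwise.append((names[i], names[j], diff, float(pvalues[i, j])))
    return AnovaResult(
        f=float(f), p=float(p),
        group_means={k: float(v.mean()) for k, v in usable.items()},
        pairwise=pairwise, dropped=dropped,
    )
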