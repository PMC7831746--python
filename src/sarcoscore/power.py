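"""Case-control power for genetic association from genotype relative risks.

Parameterization follows the classic genetic power calculator convention:
risk-allele frequency p, disease prevalence K, and genotype relative risks
g1 = f(het)/f(ref), g2 = f(hom)/f(ref).  The baseline penetrance solves

    f0 = K / (q^2 + 2 p q g1 + p^2 g2),   q = 1 - p,

and case/control genotype distributions follow by Bayes' rule.  The allelic
1-df test treats the 2N alleles per group as independent; its non-centrality
uses the unpooled two-proportion variance by default (a pooled variant is
selectable), and power is the upper tail of the non-central chi-square
beyond the central critical value at alpha.  The marker is taken to be the
causal variant itself (no linkage disequilibrium attenuation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "PowerResult", "penetrances", "group_frequencies",
           "power", "required_n"]


@dataclass(frozen=True)
class PowerSpec:
    risk_allele_freq: float
    prevalence: float
    grr_het: float
    grr_hom: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05
    test: Literal["allelic_1df", "genotypic_2df"] = "allelic_1df"
    variance: Literal["unpooled", "pooled"] = "unpooled"

    def __post_init__(self) -> None:
        if not 0 < self.risk_allele_freq < 1:
            raise ValueError("risk allele frequency must be in (0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.grr_het < 0 or self.grr_hom < 0:
            raise ValueError("genotype relative risks must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be positive")


@dataclass(frozen=True)
class PowerResult:
    f0: float
    f1: float
    f2: float
    case_genotype_freq: tuple[float, float, float]     # (hom_risk, het, hom_other)
    control_genotype_freq: tuple[float, float, float]
    case_allele_freq: float
    control_allele_freq: float
    ncp: float
    df: int
    power: float


def penetrances(spec: PowerSpec) -> tuple[float, float, float]:
    """Baseline, heterozygote and homozygote penetrances (f0, f1, f2)."""
    p, q = spec.risk_allele_freq, 1.0 - spec.risk_allele_freq
    f0 = spec.prevalence / (q * q + 2 * p * q * spec.grr_het + p * p * spec.grr_hom)
    f1, f2 = spec.grr_het * f0, spec.grr_hom * f0
    if f2 > 1.0 or f1 > 1.0:
        raise ValueError(
            f"invalid spec: implied penetrance exceeds 1 (f1={f1:.4f}, f2={f2:.4f})"
        )
    return f0, f1, f2


def group_frequencies(spec: PowerSpec) -> PowerResult:
    """Expected genotype and allele frequencies in cases and controls.

    P(g | case) = f_g P(g) / K and P(g | control) = (1 - f_g) P(g) / (1 - K)
    with P(g) the Hardy-Weinberg genotype probabilities.  The ``ncp`` and
    ``power`` fields are left at zero; :func:`power` fills them.
    """
    f0, f1, f2 = penetrances(spec)
    p, q = spec.risk_allele_freq, 1.0 - spec.risk_allele_freq
    k = spec.prevalence
    pop = np.array([p * p, 2 * p * q, q * q])
    f = np.array([f2, f1, f0])
    case = f * pop / k
    control = (1.0 - f) * pop / (1.0 - k)
    return PowerResult(
        f0=f0, f1=f1, f2=f2,
        case_genotype_freq=tuple(case),
        control_genotype_freq=tuple(control),
        case_allele_freq=float(case[0] + case[1] / 2.0),
        control_allele_freq=float(control[0] + control[1] / 2.0),
        ncp=0.0, df=1, power=0.0,
    )


def _ncp(spec: PowerSpec, freqs: PowerResult) -> tuple[float, int]:
    if spec.test == "allelic_1df":
        pa, pu = freqs.case_allele_freq, freqs.control_allele_freq
        na, nu = 2 * spec.n_cases, 2 * spec.n_controls
        if spec.variance == "unpooled":
            var = pa * (1 - pa) / na + pu * (1 - pu) / nu
        else:
            pbar = (pa * na + pu * nu) / (na + nu)
            var = pbar * (1 - pbar) * (1 / na + 1 / nu)
        return (pa - pu) ** 2 / var, 1
    # genotypic 2 df: Pearson discrepancy of the expected 2x3 table
    case = np.array(freqs.case_genotype_freq) * spec.n_cases
    control = np.array(freqs.control_genotype_freq) * spec.n_controls
    obs = np.vstack([case, control])
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - expected) ** 2 / expected).sum()), 2


def power(spec: PowerSpec) -> PowerResult:
    """Analytic power of the chi-square association test under the spec."""
    freqs = group_frequencies(spec)
    ncp, df = _ncp(spec, freqs)
    critical = stats.chi2.ppf(1.0 - spec.alpha, df)
    pw = float(stats.ncx2.sf(critical, df, ncp)) if ncp > 0 else spec.alpha
    return replace(freqs, ncp=float(ncp), df=df, power=pw)


def required_n(
    spec: PowerSpec, target_power: float, case_control_ratio: float | None = None
) -> int:
    """Smallest n_cases reaching ``target_power`` at a fixed case:control ratio.

    ``case_control_ratio`` defaults to the spec's n_controls / n_cases.
    Bisection on n_cases followed by a local scan; raises if even very large
    samples cannot attain the target (e.g. null effects).
    """
    if not spec.alpha < target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    ratio = (
        case_control_ratio
        if case_control_ratio is not None
        else spec.n_controls / spec.n_cases
    )

    def power_at(n_cases: int) -> float:
        n_cases = max(n_cases, 1)
        n_controls = max(int(round(ratio * n_cases)), 1)
        return power(replace(spec, n_cases=n_cases, n_controls=n_controls)).power

    lo, hi = 1, 2
    while power_at(hi) < target_power:
        hi *= 2
        if hi > 10_000_000:
            raise ValueError("target power unattainable under this spec")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    # local scan guards against non-monotone rounding of the control count
    n = hi
    while n > 1 and power_at(n - 1) >= target_power:
        n -= 1
    return n
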