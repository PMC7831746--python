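"""Hardy-Weinberg equilibrium tests on biallelic genotype counts.

Deviation from HWE in controls flags genotyping artefacts; per the study's
QC policy a SNP whose controls deviate is excluded from association analysis,
while deviation restricted to cases is reported (it can itself reflect
association) but does not exclude the SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import GenotypeCounts

__all__ = ["HweResult", "hwe_chisq", "hwe_exact"]


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    allele_freq: float
    expected: tuple[float, float, float]


def _check_polymorphic(counts: GenotypeCounts) -> None:
    if counts.n < 1:
        raise ValueError("HWE test needs at least one genotype")
    n_risk = counts.n_risk_alleles
    if n_risk == 0 or n_risk == 2 * counts.n:
        raise ValueError("HWE undefined for monomorphic SNP")


def hwe_chisq(counts: GenotypeCounts) -> HweResult:
    """Pearson goodness-of-fit test against HWE proportions, 1 df.

    No continuity correction, so a sample exactly at Hardy-Weinberg
    proportions yields chi2 = 0, p = 1.
    """
    _check_polymorphic(counts)
    n = counts.n
    p_hat = counts.n_risk_alleles / (2 * n)
    q_hat = 1.0 - p_hat
    expected = (n * p_hat**2, 2 * n * p_hat * q_hat, n * q_hat**2)
    observed = (counts.n_hom_risk, counts.n_het, counts.n_hom_other)
    chi2 = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    # genotype df 2 minus 1 estimated allele frequency
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p=p, allele_freq=p_hat, expected=expected)


def hwe_exact(counts: GenotypeCounts) -> float:
    """Two-sided exact HWE p-value (conditional on allele counts).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more probable
    than the observed one — the standard exact formulation for small
    samples, preferable to the chi-square test when any expected cell is
    small.
    """
    _check_polymorphic(counts)
    n = counts.n
    n_a = counts.n_risk_alleles  # rarer-or-not does not matter: symmetric
    n_b = 2 * n - n_a
    minor = min(n_a, n_b)
    # feasible heterozygote counts share the parity of the minor allele count
    het_values = np.arange(minor % 2, minor + 1, 2)
    # log P(het | allele counts) up to a shared constant:
    # P ∝ n! / (n_AA! n_AB! n_BB!) * 2^het
    n_aa = (n_a - het_values) // 2
    n_bb = (n_b - het_values) // 2
    from scipy.special import gammaln

    logp = (
        het_values * np.log(2.0)
        - gammaln(n_aa + 1)
        - gammaln(het_values + 1)
        - gammaln(n_bb + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    observed = prob[het_values == counts.n_het][0]
    return float(prob[prob <= observed * (1 + 1e-12)].sum())
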