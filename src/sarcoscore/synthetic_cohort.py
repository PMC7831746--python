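"""Synthetic case-control cohorts with known generating parameters.

The generator emulates the statistical structure the analysis pipeline
assumes: per-SNP Hardy-Weinberg genotypes in the source population, disease
assigned through a logistic liability with log-GRR genotype offsets,

    logit P(case) = b0 + sum_snp s(genotype) + covariate terms,
    s(het) = ln g1,  s(hom_risk) = ln g2,  s(hom_other) = 0,

with the intercept b0 solved by bisection so the population prevalence
matches the spec.  Cases and controls are then subsampled from a large
simulated population (default 100x the cohort), which guarantees exact group
sizes.  Phenotypes (grip, gait speed, skeletal muscle index) are drawn from
status- and sex-conditional normal distributions chosen so that EWGSOP
classification agrees with the generating status for roughly 95% of samples;
BIA resistance is back-solved from the drawn muscle index through the
Janssen equation, so the phenotype pipeline reproduces the intended SMI
exactly.  Genotypes are finally masked at the missing rate and perturbed at
the allele-error rate.

A single seed governs all randomness through deterministically spawned
substreams, so one spec + one seed always yields a byte-identical cohort.

The default scenario mirrors the published study: 45 cases / 145 controls,
67 men / 123 women, age 78.3 +/- 9.6 y, three effect SNPs calibrated to the
published control allele frequencies and allelic odds ratios, three null
SNPs, 6.5% missing genotypes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_io import CohortRecord, GenotypeCall, GenotypeCounts, SnpPanelEntry
from .phenotype import (
    JANSSEN_AGE_COEF,
    JANSSEN_IMPEDANCE_COEF,
    JANSSEN_INTERCEPT,
    JANSSEN_SEX_COEF,
)
from .power import PowerSpec, group_frequencies
from . import study

__all__ = [
    "SnpEffect",
    "PhenotypeModel",
    "SimSpec",
    "SimTruth",
    "simulate",
    "study_default_spec",
    "sample_group_genotype_counts",
    "calibrate_snp_effect",
]


@dataclass(frozen=True)
class SnpEffect:
    """Generating parameters of one SNP: population frequency and GRRs."""

    entry: SnpPanelEntry
    risk_allele_freq: float
    grr_het: float = 1.0
    grr_hom: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.risk_allele_freq < 1:
            raise ValueError(f"{self.entry.snp_id}: frequency must be in (0, 1)")
        if self.grr_het < 0 or self.grr_hom < 0:
            raise ValueError(f"{self.entry.snp_id}: GRRs must be non-negative")


@dataclass(frozen=True)
class PhenotypeModel:
    """Status/sex-conditional phenotype distributions (normal, truncated).

    SMI means/sds are in kg/m^2, grip in kg, gait in m/s.  Defaults place
    case distributions mostly below and control distributions mostly above
    the EWGSOP cutoffs (27/16 kg grip, 8.87/6.42 kg/m^2 SMI), giving ~95%
    status-classification concordance.
    """

    grip: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("male", "case"): (21.0, 3.0), ("male", "control"): (34.0, 5.0),
            ("female", "case"): (12.5, 1.8), ("female", "control"): (22.0, 4.0),
        }
    )
    smi: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("male", "case"): (7.6, 0.7), ("male", "control"): (10.2, 1.0),
            ("female", "case"): (5.5, 0.5), ("female", "control"): (7.6, 0.8),
        }
    )
    gait: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("male", "case"): (0.6, 0.15), ("male", "control"): (1.0, 0.2),
            ("female", "case"): (0.6, 0.15), ("female", "control"): (1.0, 0.2),
        }
    )
    height_cm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (172.0, 6.0), "female": (159.0, 6.0)}
    )
    mass_kg: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (74.0, 10.0), "female": (64.0, 10.0)}
    )


@dataclass(frozen=True)
class SimSpec:
    snps: tuple[SnpEffect, ...]
    n_cases: int = 45
    n_controls: int = 145
    prevalence: float = 45 / 190
    beta_age: float = 0.0          # log-odds per year (age centered at its mean)
    beta_male: float = 0.0         # log-odds for male sex
    beta_activity: float = 0.0     # log-odds per activity unit
    age_mean: float = study.AGE_MEAN
    age_sd: float = study.AGE_SD
    age_min: float = 65.0
    male_fraction: float = study.N_MEN / study.N_TOTAL
    phenotypes: PhenotypeModel = field(default_factory=PhenotypeModel)
    missing_rate: float = 0.065
    error_rate: float = 0.02
    population_multiplier: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.age_sd <= 0:
            raise ValueError("age sd must be positive")
        if not 0 <= self.missing_rate < 1 or not 0 <= self.error_rate < 1:
            raise ValueError("rates must be in [0, 1)")

    @property
    def panel(self) -> list[SnpPanelEntry]:
        return [s.entry for s in self.snps]


@dataclass
class SimTruth:
    """Generator bookkeeping for parameter-recovery tests."""

    liability: dict[str, float]                 # per emitted sample
    genotype_counts: dict[str, dict[str, GenotypeCounts]]  # pre-masking, per group
    population_prevalence: float
    intercept: float
    n_population: int


def _solve_intercept(spec: SimSpec, genotype_offset_mean_fn) -> float:
    """Bisection on b0 so that E[sigmoid(b0 + offsets)] = prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if genotype_offset_mean_fn(mid) < spec.prevalence:
            lo = mid
        else:
            hi = mid
    b0 = (lo + hi) / 2.0
    if abs(genotype_offset_mean_fn(b0) - spec.prevalence) > 1e-6:
        raise ValueError("prevalence unattainable with the requested effects")
    return b0


def _dosage_to_call(dose: int, entry: SnpPanelEntry) -> GenotypeCall:
    risk = entry.risk_allele or entry.allele_pair[0]
    a, b = entry.allele_pair
    other = b if risk == a else a
    alleles = [risk] * dose + [other] * (2 - dose)
    return GenotypeCall(alleles[0], alleles[1])


def simulate(spec: SimSpec) -> tuple[list[CohortRecord], SimTruth]:
    """Draw one cohort under ``spec``; returns records plus generator truth."""
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_geno, rng_status, rng_demo, rng_pheno, rng_miss, rng_err = (
        np.random.default_rng(s) for s in streams
    )

    n_pop = spec.population_multiplier * (spec.n_cases + spec.n_controls)
    k = len(spec.snps)

    doses = np.empty((n_pop, k), dtype=np.int64)
    offsets = np.zeros(n_pop)
    for j, snp in enumerate(spec.snps):
        doses[:, j] = rng_geno.binomial(2, snp.risk_allele_freq, size=n_pop)
        table = np.array([0.0, np.log(snp.grr_het), np.log(snp.grr_hom)])
        offsets += table[doses[:, j]]

    male = rng_demo.random(n_pop) < spec.male_fraction
    age = spec.age_mean + spec.age_sd * rng_demo.standard_normal(n_pop)
    # truncate the age distribution at the cohort minimum by reflection
    age = np.where(age < spec.age_min, 2 * spec.age_min - age, age)
    activity = rng_demo.standard_normal(n_pop)
    offsets = (
        offsets
        + spec.beta_age * (age - spec.age_mean)
        + spec.beta_male * male
        + spec.beta_activity * activity
    )

    def mean_prob(b0: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(b0 + offsets)))).mean())

    b0 = _solve_intercept(spec, mean_prob)
    prob = 1.0 / (1.0 + np.exp(-(b0 + offsets)))
    is_case = rng_status.random(n_pop) < prob

    case_idx = np.flatnonzero(is_case)
    control_idx = np.flatnonzero(~is_case)
    if len(case_idx) < spec.n_cases or len(control_idx) < spec.n_controls:
        raise ValueError(
            "simulated population too small for the requested group sizes; "
            "raise population_multiplier"
        )
    chosen_cases = rng_status.choice(case_idx, size=spec.n_cases, replace=False)
    chosen_controls = rng_status.choice(control_idx, size=spec.n_controls, replace=False)
    chosen = np.concatenate([chosen_cases, chosen_controls])
    status = ["sarcopenic"] * spec.n_cases + ["non_sarcopenic"] * spec.n_controls

    # ---- generator truth, recorded before masking/error perturbation
    truth_counts: dict[str, dict[str, GenotypeCounts]] = {}
    for j, snp in enumerate(spec.snps):
        per_group = {}
        for label, idx in (("sarcopenic", chosen_cases), ("non_sarcopenic", chosen_controls)):
            d = doses[idx, j]
            per_group[label] = GenotypeCounts(
                int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())
            )
        truth_counts[snp.entry.snp_id] = per_group

    # ---- phenotypes conditional on emitted status and sex
    n = len(chosen)
    records: list[CohortRecord] = []
    liability: dict[str, float] = {}
    pm = spec.phenotypes
    draw = rng_pheno.standard_normal((n, 5))  # grip, smi, gait, height, mass
    mask = rng_miss.random((n, k)) < spec.missing_rate
    err = rng_err.random((n, k)) < spec.error_rate
    err_dir = rng_err.random((n, k))

    for i, idx in enumerate(chosen):
        sex = "male" if male[idx] else "female"
        cond = "case" if status[i] == "sarcopenic" else "control"
        g_mu, g_sd = pm.grip[(sex, cond)]
        s_mu, s_sd = pm.smi[(sex, cond)]
        w_mu, w_sd = pm.gait[(sex, cond)]
        h_mu, h_sd = pm.height_cm[sex]
        m_mu, m_sd = pm.mass_kg[sex]
        grip = max(g_mu + g_sd * draw[i, 0], 1.0)
        smi = max(s_mu + s_sd * draw[i, 1], 3.0)
        gait = max(w_mu + w_sd * draw[i, 2], 0.1)
        height = max(h_mu + h_sd * draw[i, 3], 120.0)
        mass = max(m_mu + m_sd * draw[i, 4], 30.0)
        # invert the Janssen equation so the drawn SMI is reproduced exactly
        smm = smi * (height / 100.0) ** 2
        denom = (
            smm
            - JANSSEN_SEX_COEF * (sex == "male")
            - JANSSEN_AGE_COEF * age[idx]
            - JANSSEN_INTERCEPT
        )
        resistance = JANSSEN_IMPEDANCE_COEF * height**2 / denom

        genotypes: dict[str, GenotypeCall] = {}
        for j, snp in enumerate(spec.snps):
            if mask[i, j]:
                genotypes[snp.entry.snp_id] = GenotypeCall.missing()
                continue
            dose = int(doses[idx, j])
            if err[i, j]:
                # single-allele call error: move one step on the dosage scale
                if dose == 0:
                    dose = 1
                elif dose == 2:
                    dose = 1
                else:
                    dose = 0 if err_dir[i, j] < 0.5 else 2
            genotypes[snp.entry.snp_id] = _dosage_to_call(dose, snp.entry)

        sample_id = f"S{i + 1:04d}"
        liability[sample_id] = float(b0 + offsets[idx])
        records.append(
            CohortRecord(
                sample_id=sample_id,
                sex=sex,
                age=float(round(age[idx], 1)),
                height_cm=float(round(height, 1)),
                mass_kg=float(round(mass, 1)),
                resistance_ohm=float(round(resistance, 1)),
                grip_kg=float(round(grip, 1)),
                gait_m_s=float(round(gait, 2)),
                physical_activity=float(round(activity[idx], 3)),
                status=status[i],
                genotypes=genotypes,
            )
        )

    truth = SimTruth(
        liability=liability,
        genotype_counts=truth_counts,
        population_prevalence=float(is_case.mean()),
        intercept=b0,
        n_population=n_pop,
    )
    return records, truth


# ---------------------------------------------------------------------------
# fast replicate sampling for operating-characteristic studies


def sample_group_genotype_counts(
    risk_allele_freq: float,
    grr_het: float,
    grr_hom: float,
    prevalence: float,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (size, 3) case and control genotype-count arrays directly.

    Counts are multinomial draws from the exact status-conditional genotype
    distributions of the penetrance model — the distribution the full
    population-and-subsample generator converges to — which makes thousands
    of replicates cheap for type-I error, coverage and power studies.
    Columns are (hom_risk, het, hom_other).
    """
    freqs = group_frequencies(
        PowerSpec(
            risk_allele_freq=risk_allele_freq, prevalence=prevalence,
            grr_het=grr_het, grr_hom=grr_hom,
            n_cases=n_cases, n_controls=n_controls,
        )
    )
    case = rng.multinomial(n_cases, freqs.case_genotype_freq, size=size)
    control = rng.multinomial(n_controls, freqs.control_genotype_freq, size=size)
    return case, control


# ---------------------------------------------------------------------------
# study-default scenario


def liability_group_freqs(
    pop_freq: float, g1: float, g2: float, prevalence: float
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Case/control genotype distributions under the logistic liability model.

    Genotype probabilities are Hardy-Weinberg; P(case | genotype) is a
    logistic in the log-GRR offsets with the intercept solved so the
    population prevalence matches.  Returns (case, control) triples ordered
    (hom_risk, het, hom_other) — the exact conditional distributions of the
    cohort generator, used to calibrate it.
    """
    import math

    p, q = pop_freq, 1.0 - pop_freq
    w = (p * p, 2 * p * q, q * q)
    s = (math.log(g2), math.log(g1), 0.0)

    def prev(b0: float) -> float:
        return sum(wg / (1.0 + math.exp(-(b0 + sg))) for wg, sg in zip(w, s))

    lo, hi = -40.0, 40.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if prev(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    b0 = (lo + hi) / 2.0
    pcase = [wg / (1.0 + math.exp(-(b0 + sg))) for wg, sg in zip(w, s)]
    case = tuple(v / prevalence for v in pcase)
    control = tuple((wg - v) / (1.0 - prevalence) for wg, v in zip(w, pcase))
    return case, control  # type: ignore[return-value]


def _allelic_or(pop_freq: float, g1: float, g2: float, prevalence: float) -> tuple[float, float]:
    """(allelic OR, control allele freq) implied by the liability model."""
    case, control = liability_group_freqs(pop_freq, g1, g2, prevalence)
    pa = case[0] + case[1] / 2.0
    pu = control[0] + control[1] / 2.0
    return (pa / (1 - pa)) / (pu / (1 - pu)), pu


def calibrate_snp_effect(
    target_control_freq: float,
    target_allelic_or: float,
    prevalence: float,
) -> tuple[float, float]:
    """Population frequency and multiplicative GRR hitting the targets.

    Under a multiplicative model (g2 = g1^2) the target allelic OR and
    control allele frequency pin down (population frequency, g1); both are
    solved by nested bisection on the liability-model expectations, so the
    calibration matches the generator's own disease model.
    """

    def solve_pop_freq(g1: float) -> float:
        lo, hi = 1e-4, 1 - 1e-4
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if _allelic_or(mid, g1, g1 * g1, prevalence)[1] < target_control_freq:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    lo, hi = 1.0, 50.0
    for _ in range(60):
        g1 = (lo + hi) / 2.0
        pop = solve_pop_freq(g1)
        if _allelic_or(pop, g1, g1 * g1, prevalence)[0] < target_allelic_or:
            lo = g1
        else:
            hi = g1
    g1 = (lo + hi) / 2.0
    return solve_pop_freq(g1), g1


def implied_group_distributions(
    snps: Sequence[SnpEffect], prevalence: float
) -> dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]:
    """Exact per-SNP case/control genotype distributions of the joint model.

    Enumerates the 3^K joint genotype lattice of the logistic liability (all
    SNPs together, covariate effects at their default of zero), solves the
    intercept for the population prevalence, and marginalizes.  Triples are
    ordered (hom_risk, het, hom_other) — the quantities the generator's
    case/control subsampling converges to, hence the calibration target and
    the reference for parameter-recovery checks.
    """
    k = len(snps)
    shape = [3] * k
    weight = np.ones(shape)
    offset = np.zeros(shape)
    for j, snp in enumerate(snps):
        p = snp.risk_allele_freq
        w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])  # dose 0,1,2
        s = np.array([0.0, np.log(snp.grr_het), np.log(snp.grr_hom)])
        dims = [3 if i == j else 1 for i in range(k)]
        weight = weight * w.reshape(dims)
        offset = offset + s.reshape(dims)

    def prev(b0: float) -> float:
        return float((weight / (1.0 + np.exp(-(b0 + offset)))).sum())

    lo, hi = -40.0, 40.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if prev(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    b0 = (lo + hi) / 2.0
    joint_case = weight / (1.0 + np.exp(-(b0 + offset)))
    k_real = joint_case.sum()
    joint_control = weight - joint_case

    out = {}
    for j, snp in enumerate(snps):
        axes = tuple(i for i in range(k) if i != j)
        case = joint_case.sum(axis=axes) / k_real          # indexed by dose 0,1,2
        control = joint_control.sum(axis=axes) / (1.0 - k_real)
        out[snp.entry.snp_id] = (
            (float(case[2]), float(case[1]), float(case[0])),
            (float(control[2]), float(control[1]), float(control[0])),
        )
    return out


def _calibrate_joint(
    panel: dict[str, SnpPanelEntry],
    targets: dict[str, tuple[float, float]],
    null_freqs: dict[str, float],
    prevalence: float,
    sweeps: int = 8,
) -> tuple[SnpEffect, ...]:
    """Per-SNP (population frequency, multiplicative GRR) hitting the targets
    jointly: marginal control allele frequency and marginal allelic OR of
    every effect SNP match its target in the presence of the other SNPs.

    Coordinate-wise bisection over the exact joint-model marginals; a
    handful of sweeps converges because cross-SNP coupling is weak once each
    SNP is near its own target.
    """
    snps: list[SnpEffect] = []
    for snp_id, (ctrl_freq, or_target) in targets.items():
        pop_freq, g1 = calibrate_snp_effect(ctrl_freq, or_target, prevalence)
        snps.append(SnpEffect(panel[snp_id], pop_freq, g1, g1 * g1))
    for snp_id, freq in null_freqs.items():
        entry = panel[snp_id]
        if entry.risk_allele is None:
            entry = dataclasses.replace(entry, risk_allele=entry.allele_pair[0])
        snps.append(SnpEffect(entry, freq))

    def marginals(j: int) -> tuple[float, float]:
        dists = implied_group_distributions(snps, prevalence)
        case, control = dists[snps[j].entry.snp_id]
        pa = case[0] + case[1] / 2.0
        pu = control[0] + control[1] / 2.0
        return (pa / (1 - pa)) / (pu / (1 - pu)), pu

    for _ in range(sweeps):
        for j, snp in enumerate(snps):
            if snp.entry.snp_id not in targets:
                continue
            ctrl_target, or_target = targets[snp.entry.snp_id]
            lo, hi = 1e-3, 1 - 1e-3
            for _ in range(40):
                mid = (lo + hi) / 2.0
                snps[j] = dataclasses.replace(snp, risk_allele_freq=mid)
                if marginals(j)[1] < ctrl_target:
                    lo = mid
                else:
                    hi = mid
            snp = snps[j]
            lo, hi = 1.0, 50.0
            for _ in range(40):
                mid = (lo + hi) / 2.0
                snps[j] = dataclasses.replace(snp, grr_het=mid, grr_hom=mid * mid)
                if marginals(j)[0] < or_target:
                    lo = mid
                else:
                    hi = mid
            snp = snps[j]
    return tuple(snps)


_STUDY_TARGETS = {
    "rs1801131": (0.283, 3.317),
    "rs1815739": (0.424, 2.037),
    "rs12594956": (0.486, 1.915),
}
_STUDY_NULL_FREQS = {"rs2228570": 0.623, "rs1042713": 0.616, "rs7947391": 0.379}
_STUDY_SNPS_CACHE: tuple[SnpEffect, ...] | None = None


def study_default_spec(seed: int = 0) -> SimSpec:
    """The published cohort's structure as a generator spec.

    45 cases / 145 controls, three effect SNPs whose control risk-allele
    frequencies and allelic odds ratios are calibrated to the published
    values (MTHFR C: 0.283 / OR 3.317; ACTN3 X: 0.424 / OR 2.037; NRF2 C:
    0.486 / OR 1.915, multiplicative GRRs, calibrated jointly so the
    marginals hold with all SNPs in the liability), plus three null SNPs at
    the published total-sample frequencies.  CX3CR1, which the study
    excluded after its Hardy-Weinberg failure, is omitted; genotypes here
    are in HWE by construction.
    """
    global _STUDY_SNPS_CACHE
    if _STUDY_SNPS_CACHE is None:
        prevalence = study.N_CASES / study.N_TOTAL
        panel = {e.snp_id: e for e in study.STUDY_PANEL}
        _STUDY_SNPS_CACHE = _calibrate_joint(
            panel, _STUDY_TARGETS, _STUDY_NULL_FREQS, prevalence
        )
    return SimSpec(snps=_STUDY_SNPS_CACHE, seed=seed)
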