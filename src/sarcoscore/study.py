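"""Published summary statistics of the nursing-home sarcopenia cohort.

These constants are the printed inputs of the study: the seven-SNP candidate
panel, group sizes, and the case/control risk-allele frequencies of the three
SNPs that entered the genetic risk score.  They let the desk-scale analyses
(allele-count reconstruction, odds ratios, power) run without the deposited
individual-level dataset, and they parameterize the synthetic-cohort
generator's default scenario.
"""

from __future__ import annotations

from .cohort_io import SnpPanelEntry

#: Total participants and EWGSOP case split.
N_TOTAL = 190
N_CASES = 45
N_CONTROLS = 145
N_MEN = 67
N_WOMEN = 123
AGE_MEAN = 78.3
AGE_SD = 9.6

#: The seven-SNP candidate panel.  ACTN3 rs1815739 is C/T at the nucleotide
#: level; the conventional R/X protein labels ride along as display labels
#: (T = 577X, the stop allele).
STUDY_PANEL: tuple[SnpPanelEntry, ...] = (
    SnpPanelEntry("rs1801131", "MTHFR", "1p36.22", ("A", "C"), "C"),
    SnpPanelEntry("rs1815739", "ACTN3", "11q13.2", ("C", "T"), "T",
                  label_map={"C": "R", "T": "X"}),
    SnpPanelEntry("rs12594956", "NRF2", "15q21.2", ("A", "C"), "C"),
    SnpPanelEntry("rs2228570", "VDR", "12q13.11", ("C", "T"), None),
    SnpPanelEntry("rs1042713", "ADRB2", "5q32", ("A", "G"), None),
    SnpPanelEntry("rs3732379", "CX3CR1", "3p22.2", ("C", "T"), None),
    SnpPanelEntry("rs7947391", "NPAS4", "11q13.2", ("A", "G"), None),
)

#: Published case/control risk-allele frequencies (percent) for the three
#: score SNPs; the substrate for allele-count reconstruction.
REPORTED_ALLELE_FREQ_PERCENT: dict[str, tuple[float, float]] = {
    "rs1801131": (56.7, 28.3),   # MTHFR C allele, cases vs controls
    "rs1815739": (60.0, 42.4),   # ACTN3 X (T) allele
    "rs12594956": (64.4, 48.6),  # NRF2 C allele
}

#: rsIDs of the three SNPs combined into the genetic risk score.
SCORE_SNPS = ("rs1801131", "rs1815739", "rs12594956")

#: Genotyping amplification (call) rate of the KASP assay.
CALL_RATE = 0.935

#: Parameters of the published a-priori power calculation.
POWER_PARAMETERS = dict(
    n_cases=50,
    n_controls=150,
    risk_allele_freq=0.4,
    prevalence=0.25,
    grr_het=1.5,
    grr_hom=2.5,
    alpha=0.05,
)
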