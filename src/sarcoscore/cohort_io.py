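"""Cohort data model, panel configuration, and table readers/writers.

The central objects are :class:`SnpPanelEntry` (one biallelic SNP of the
candidate panel), :class:`GenotypeCall` (one sample's unphased call at one
SNP), and :class:`CohortRecord` (one participant with demographics,
anthropometrics, functional measures and genotype calls).  All association
and scoring modules consume genotype counts produced here.

Genotype cells are written ``"X/Y"``; heterozygotes are stored canonically
with alleles in alphabetical order.  Empty cells, ``NA`` and ``./.`` are all
accepted as missing on read; ``NA`` is the canonical missing marker on write.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SnpPanelEntry",
    "GenotypeCall",
    "CohortRecord",
    "GenotypeCounts",
    "MISSING_MARKERS",
    "COHORT_COLUMNS",
    "PanelError",
    "CohortValidationError",
    "read_panel",
    "write_panel",
    "read_cohort",
    "write_cohort",
    "call_rate_summary",
    "genotype_dosage",
    "genotype_counts",
    "import_vcf",
]

#: Cell contents interpreted as a missing genotype on read.
MISSING_MARKERS = frozenset({"", "NA", "N/A", "./.", ".|.", "."})

#: Fixed, canonical order of the non-genotype cohort-table columns.
COHORT_COLUMNS = (
    "sample_id",
    "sex",
    "age",
    "height_cm",
    "mass_kg",
    "resistance_ohm",
    "grip_kg",
    "gait_m_s",
    "physical_activity",
    "status",
)

STATUSES = ("sarcopenic", "non_sarcopenic", "unclassified")


class PanelError(ValueError):
    """Malformed or inconsistent SNP panel configuration."""


class CohortValidationError(ValueError):
    """A cohort table cell violates the data-model invariants."""


@dataclass(frozen=True)
class SnpPanelEntry:
    """One biallelic SNP of the candidate panel.

    ``allele_pair`` holds nucleotide alleles (the keys genotypes are coded
    by); ``label_map`` optionally maps nucleotides to display labels such as
    the R/X convention for the ACTN3 R577X stop polymorphism.
    """

    snp_id: str
    gene: str
    locus: str
    allele_pair: tuple[str, str]
    risk_allele: str | None = None
    label_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.allele_pair) != 2 or len(set(self.allele_pair)) != 2:
            raise PanelError(
                f"{self.snp_id}: allele_pair must be two distinct alleles, "
                f"got {self.allele_pair!r}"
            )
        if self.risk_allele is not None and self.risk_allele not in self.allele_pair:
            raise PanelError(
                f"{self.snp_id}: risk_allele {self.risk_allele!r} not in "
                f"allele pair {self.allele_pair!r}"
            )

    @property
    def other_allele(self) -> str | None:
        if self.risk_allele is None:
            return None
        a, b = self.allele_pair
        return b if self.risk_allele == a else a

    def label(self, allele: str) -> str:
        return self.label_map.get(allele, allele)


@dataclass(frozen=True)
class GenotypeCall:
    """Unphased biallelic genotype call; both alleles present or both None."""

    allele1: str | None
    allele2: str | None

    def __post_init__(self) -> None:
        if (self.allele1 is None) != (self.allele2 is None):
            raise CohortValidationError(
                "half-missing genotype call: both alleles must be present or absent"
            )
        # canonical ordering so A/C == C/A
        if self.allele1 is not None and self.allele2 is not None:
            if self.allele1 > self.allele2:
                a1, a2 = self.allele2, self.allele1
                object.__setattr__(self, "allele1", a1)
                object.__setattr__(self, "allele2", a2)

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls(None, None)

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.allele1 != self.allele2

    def to_text(self) -> str:
        if self.is_missing:
            return "NA"
        return f"{self.allele1}/{self.allele2}"

    @classmethod
    def from_text(cls, cell: str, entry: SnpPanelEntry | None = None) -> "GenotypeCall":
        cell = cell.strip()
        if cell in MISSING_MARKERS:
            return cls.missing()
        sep = "/" if "/" in cell else "|" if "|" in cell else None
        if sep is None:
            raise CohortValidationError(f"cannot parse genotype cell {cell!r}")
        a1, a2 = (part.strip() for part in cell.split(sep, 1))
        if entry is not None:
            for a in (a1, a2):
                if a not in entry.allele_pair:
                    raise CohortValidationError(
                        f"allele {a!r} not in panel pair {entry.allele_pair!r} "
                        f"for {entry.snp_id}"
                    )
        return cls(a1, a2)


@dataclass
class CohortRecord:
    """One study participant."""

    sample_id: str
    sex: str  # "male" | "female"
    age: float
    height_cm: float | None = None
    mass_kg: float | None = None
    resistance_ohm: float | None = None
    grip_kg: float | None = None
    gait_m_s: float | None = None
    physical_activity: float | None = None
    status: str = "unclassified"
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def validate(self, panel: Sequence[SnpPanelEntry], min_age: float = 65.0) -> None:
        if self.sex not in ("male", "female"):
            raise CohortValidationError(f"{self.sample_id}: sex must be male/female")
        if self.status not in STATUSES:
            raise CohortValidationError(f"{self.sample_id}: unknown status {self.status!r}")
        if self.age < min_age:
            raise CohortValidationError(
                f"{self.sample_id}: age {self.age} below cohort minimum {min_age}"
            )
        for name in ("height_cm", "mass_kg", "resistance_ohm", "grip_kg", "gait_m_s"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise CohortValidationError(
                    f"{self.sample_id}: {name} must be positive, got {value}"
                )
        panel_ids = {e.snp_id for e in panel}
        unknown = set(self.genotypes) - panel_ids
        if unknown:
            raise CohortValidationError(
                f"{self.sample_id}: genotype keys not in panel: {sorted(unknown)}"
            )


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts oriented by a reference allele (hom/het/other-hom)."""

    n_hom_risk: int
    n_het: int
    n_hom_other: int

    def __post_init__(self) -> None:
        if min(self.n_hom_risk, self.n_het, self.n_hom_other) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_other

    @property
    def n_risk_alleles(self) -> int:
        return 2 * self.n_hom_risk + self.n_het

    def frequencies(self) -> tuple[float, float, float]:
        if self.n == 0:
            raise ValueError("no genotypes counted")
        return (self.n_hom_risk / self.n, self.n_het / self.n, self.n_hom_other / self.n)

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_hom_risk + other.n_hom_risk,
            self.n_het + other.n_het,
            self.n_hom_other + other.n_hom_other,
        )


# ---------------------------------------------------------------------------
# panel configuration


def read_panel(path: str | Path) -> list[SnpPanelEntry]:
    """Read a SNP panel config (INI-style, one ``[rsID]`` section per SNP).

    Keys per section: ``gene``, ``locus``, ``alleles`` (``A/C``),
    ``risk_allele`` (optional; ``undetermined`` allowed), ``label_map``
    (optional; ``C=R,T=X``).  Duplicate rsIDs and risk alleles outside the
    pair are errors.
    """
    parser = configparser.ConfigParser(strict=True)
    try:
        with open(path, encoding="utf-8") as fh:
            parser.read_file(fh, source=str(path))
    except configparser.DuplicateSectionError as exc:
        raise PanelError(f"duplicate SNP id in panel: {exc.section!r}") from exc
    except configparser.Error as exc:
        raise PanelError(f"malformed panel file: {exc}") from exc

    entries: list[SnpPanelEntry] = []
    for snp_id in parser.sections():
        section = parser[snp_id]
        try:
            alleles = tuple(a.strip() for a in section["alleles"].split("/"))
        except KeyError as exc:
            raise PanelError(f"{snp_id}: missing required key {exc}") from exc
        risk = section.get("risk_allele", "").strip() or None
        if risk is not None and risk.lower() == "undetermined":
            risk = None
        label_map: dict[str, str] = {}
        for pair in filter(None, (p.strip() for p in section.get("label_map", "").split(","))):
            nucleotide, _, label = pair.partition("=")
            label_map[nucleotide.strip()] = label.strip()
        entries.append(
            SnpPanelEntry(
                snp_id=snp_id,
                gene=section.get("gene", ""),
                locus=section.get("locus", ""),
                allele_pair=alleles,  # type: ignore[arg-type]
                risk_allele=risk,
                label_map=label_map,
            )
        )
    return entries


def write_panel(entries: Sequence[SnpPanelEntry], path: str | Path) -> None:
    lines = []
    for e in entries:
        lines.append(f"[{e.snp_id}]")
        lines.append(f"gene = {e.gene}")
        lines.append(f"locus = {e.locus}")
        lines.append(f"alleles = {e.allele_pair[0]}/{e.allele_pair[1]}")
        lines.append(f"risk_allele = {e.risk_allele or 'undetermined'}")
        if e.label_map:
            lines.append(
                "label_map = " + ",".join(f"{k}={v}" for k, v in sorted(e.label_map.items()))
            )
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# cohort tables


def _parse_number(cell, column: str, sample_id: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text in MISSING_MARKERS:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise CohortValidationError(
            f"{sample_id}: non-numeric value {cell!r} in column {column!r}"
        ) from exc


def read_cohort(
    path: str | Path,
    panel: Sequence[SnpPanelEntry],
    *,
    min_age: float = 65.0,
    validate: bool = True,
) -> list[CohortRecord]:
    """Read a cohort CSV/TSV (delimiter sniffed from the header line).

    Genotype columns are named by rsID; missing cells become missing calls.
    Raises :class:`CohortValidationError` naming the sample and column on any
    unparseable cell.
    """
    path = Path(path)
    sep = "\t" if "\t" in path.read_text(encoding="utf-8").splitlines()[0] else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortValidationError(f"cohort table lacks columns: {missing_cols}")
    by_id = {e.snp_id: e for e in panel}

    records: list[CohortRecord] = []
    for row in frame.to_dict("records"):
        sample_id = str(row["sample_id"])
        genotypes: dict[str, GenotypeCall] = {}
        for snp_id, entry in by_id.items():
            cell = str(row.get(snp_id, ""))
            try:
                genotypes[snp_id] = GenotypeCall.from_text(cell, entry)
            except CohortValidationError as exc:
                raise CohortValidationError(f"sample {sample_id}, {snp_id}: {exc}") from exc
        status = str(row["status"]).strip() or "unclassified"
        record = CohortRecord(
            sample_id=sample_id,
            sex=str(row["sex"]).strip().lower(),
            age=_parse_number(row["age"], "age", sample_id) or 0.0,
            height_cm=_parse_number(row["height_cm"], "height_cm", sample_id),
            mass_kg=_parse_number(row["mass_kg"], "mass_kg", sample_id),
            resistance_ohm=_parse_number(row["resistance_ohm"], "resistance_ohm", sample_id),
            grip_kg=_parse_number(row["grip_kg"], "grip_kg", sample_id),
            gait_m_s=_parse_number(row["gait_m_s"], "gait_m_s", sample_id),
            physical_activity=_parse_number(
                row["physical_activity"], "physical_activity", sample_id
            ),
            status=status,
            genotypes=genotypes,
        )
        if validate:
            record.validate(panel, min_age=min_age)
        records.append(record)
    return records


def write_cohort(
    records: Iterable[CohortRecord],
    path: str | Path,
    panel: Sequence[SnpPanelEntry],
) -> None:
    """Write records as CSV in canonical column order (round-trips with read)."""

    def fmt(value: float | None) -> str:
        if value is None:
            return "NA"
        return format(value, "g")

    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "sex": r.sex,
            "age": fmt(r.age),
            "height_cm": fmt(r.height_cm),
            "mass_kg": fmt(r.mass_kg),
            "resistance_ohm": fmt(r.resistance_ohm),
            "grip_kg": fmt(r.grip_kg),
            "gait_m_s": fmt(r.gait_m_s),
            "physical_activity": fmt(r.physical_activity),
            "status": r.status,
        }
        for e in panel:
            row[e.snp_id] = r.genotypes.get(e.snp_id, GenotypeCall.missing()).to_text()
        rows.append(row)
    columns = list(COHORT_COLUMNS) + [e.snp_id for e in panel]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def call_rate_summary(
    records: Sequence[CohortRecord],
    panel: Sequence[SnpPanelEntry],
    *,
    flag_below: float = 0.90,
) -> pd.DataFrame:
    """Per-SNP call rate; SNPs below ``flag_below`` are flagged, not dropped."""
    rows = []
    n = len(records)
    for e in panel:
        called = sum(
            1
            for r in records
            if not r.genotypes.get(e.snp_id, GenotypeCall.missing()).is_missing
        )
        rate = called / n if n else float("nan")
        rows.append(
            {"snp_id": e.snp_id, "n_called": called, "n_total": n,
             "call_rate": rate, "flagged": bool(n and rate < flag_below)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dosage and counting


def genotype_dosage(call: GenotypeCall, risk_allele: str | None) -> int | None:
    """Count risk-allele copies (0/1/2); missing in, missing (None) out."""
    if risk_allele is None:
        raise ValueError(
            "risk allele undetermined: orient the panel via the association "
            "module (orient_risk_alleles) before computing dosages"
        )
    if call.is_missing:
        return None
    return (call.allele1 == risk_allele) + (call.allele2 == risk_allele)


def genotype_counts(
    records: Sequence[CohortRecord],
    snp_id: str,
    entry: SnpPanelEntry,
    *,
    by_status: bool = False,
) -> GenotypeCounts | dict[str, GenotypeCounts]:
    """Tally hom-risk/het/hom-other calls, optionally split by case status.

    Counts are oriented by ``entry.risk_allele``; with the risk allele
    undetermined, the first allele of the pair is the counting reference.
    """
    reference = entry.risk_allele or entry.allele_pair[0]

    def tally(group: Iterable[CohortRecord]) -> GenotypeCounts:
        hom_r = het = hom_o = 0
        for record in group:
            call = record.genotypes.get(snp_id, GenotypeCall.missing())
            if call.is_missing:
                continue
            dose = (call.allele1 == reference) + (call.allele2 == reference)
            if dose == 2:
                hom_r += 1
            elif dose == 1:
                het += 1
            else:
                hom_o += 1
        return GenotypeCounts(hom_r, het, hom_o)

    if not by_status:
        counts = tally(records)
        if counts.n == 0:
            raise ValueError(f"{snp_id}: zero non-missing genotype calls")
        return counts
    grouped = {
        status: tally(r for r in records if r.status == status)
        for status in ("sarcopenic", "non_sarcopenic")
    }
    if sum(c.n for c in grouped.values()) == 0:
        raise ValueError(f"{snp_id}: zero non-missing genotype calls")
    return grouped


# ---------------------------------------------------------------------------
# VCF import


def import_vcf(
    path: str | Path, panel: Sequence[SnpPanelEntry]
) -> tuple[dict[str, dict[str, GenotypeCall]], list[str]]:
    """Import genotypes for panel SNPs from a VCF 4.x file.

    Records are matched by ID.  GT indices map onto REF/ALT; phased
    separators are accepted and phase discarded.  Returns
    ``(genotypes_by_sample, warnings)``; panel SNPs absent from the VCF
    produce a warning and missing calls.
    """
    import pysam

    by_id = {e.snp_id: e for e in panel}
    seen: set[str] = set()
    warnings: list[str] = []
    result: dict[str, dict[str, GenotypeCall]] = {}

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for sample in samples:
            result[sample] = {e.snp_id: GenotypeCall.missing() for e in panel}
        for rec in vcf:
            if rec.id not in by_id:
                continue
            entry = by_id[rec.id]
            if rec.alts is None or len(rec.alts) != 1:
                raise CohortValidationError(
                    f"{rec.id}: panel SNPs must be biallelic in the VCF "
                    f"(REF {rec.ref}, ALT {rec.alts})"
                )
            alleles = (rec.ref, rec.alts[0])
            for allele in alleles:
                if allele not in entry.allele_pair:
                    raise CohortValidationError(
                        f"{rec.id}: VCF allele {allele!r} not in panel pair "
                        f"{entry.allele_pair!r}"
                    )
            seen.add(rec.id)
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(idx is None for idx in gt):
                    continue
                a1, a2 = (alleles[idx] for idx in gt)
                result[sample][rec.id] = GenotypeCall(a1, a2)
    for snp_id in by_id:
        if snp_id not in seen:
            warnings.append(f"panel SNP {snp_id} absent from VCF; calls left missing")
    return result, warnings


def with_status(record: CohortRecord, status: str) -> CohortRecord:
    """Return a copy of ``record`` with ``status`` replaced."""
    return replace(record, status=status)
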