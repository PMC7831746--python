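"""Panel/cohort parsing, genotype calls, dosage recoding and counting."""

import textwrap

import pytest

from sarcoscore.cohort_io import (
    CohortValidationError,
    GenotypeCall,
    GenotypeCounts,
    CohortRecord,
    PanelError,
    SnpPanelEntry,
    call_rate_summary,
    genotype_counts,
    genotype_dosage,
    import_vcf,
    read_cohort,
    read_panel,
    write_cohort,
)


class TestPanel:
    def test_study_panel_roundtrip(self, panel_file):
        entries = read_panel(panel_file)
        assert len(entries) == 7
        by_id = {e.snp_id: e for e in entries}
        mthfr = by_id["rs1801131"]
        assert mthfr.gene == "MTHFR"
        assert mthfr.allele_pair == ("A", "C")
        assert mthfr.risk_allele == "C"
        actn3 = by_id["rs1815739"]
        assert actn3.label(actn3.risk_allele) == "X"  # T is the 577X stop allele

    def test_empty_file_gives_empty_panel(self, tmp_path):
        path = tmp_path / "empty.ini"
        path.write_text("")
        assert read_panel(path) == []

    def test_duplicate_snp_id_is_error(self, tmp_path):
        path = tmp_path / "dup.ini"
        block = "[rs1801131]\ngene = MTHFR\nlocus = 1p36\nalleles = A/C\n"
        path.write_text(block + block)
        with pytest.raises(PanelError, match="duplicate"):
            read_panel(path)

    def test_risk_allele_outside_pair_rejected(self):
        with pytest.raises(PanelError, match="risk_allele"):
            SnpPanelEntry("rs1", "G1", "1q", ("A", "C"), "T")


class TestGenotypeCall:
    @pytest.mark.parametrize(
        "cell, expected",
        [
            ("A/C", ("A", "C")),
            ("C/A", ("A", "C")),  # canonical alphabetical order
            ("A|C", ("A", "C")),
            ("C/C", ("C", "C")),
            ("NA", (None, None)),
            ("", (None, None)),
            ("./.", (None, None)),
        ],
    )
    def test_parsing(self, cell, expected):
        call = GenotypeCall.from_text(cell)
        assert (call.allele1, call.allele2) == expected

    def test_allele_outside_panel_pair_rejected(self, panel):
        with pytest.raises(CohortValidationError, match="not in panel pair"):
            GenotypeCall.from_text("A/G", panel[0])

    def test_half_missing_rejected(self):
        with pytest.raises(CohortValidationError):
            GenotypeCall("A", None)


COHORT_CSV = textwrap.dedent(
    """\
    sample_id,sex,age,height_cm,mass_kg,resistance_ohm,grip_kg,gait_m_s,physical_activity,status,rs1801131,rs1815739,rs12594956,rs2228570,rs1042713,rs3732379,rs7947391
    S1,male,78,170,75,500,30,1.1,0.2,non_sarcopenic,A/C,C/T,A/A,C/C,A/G,C/T,A/G
    S2,female,81,158,60,610,14,0.7,-0.4,sarcopenic,C/C,T/T,A/C,NA,G/G,C/C,G/G
    S3,female,69,162,66,580,22,1.0,1.1,unclassified,,C/C,C/C,C/T,A/A,T/T,A/A
    """
)


class TestCohortTable:
    def test_read_small_fixture(self, tmp_path, panel):
        path = tmp_path / "cohort.csv"
        path.write_text(COHORT_CSV)
        records = read_cohort(path, panel)
        assert len(records) == 3
        assert records[0].genotypes["rs1801131"].is_het
        assert records[2].genotypes["rs1801131"].is_missing
        rates = call_rate_summary(records, panel).set_index("snp_id")
        assert rates.loc["rs1801131", "n_called"] == 2
        assert rates.loc["rs1815739", "call_rate"] == 1.0

    def test_unknown_allele_names_sample_and_snp(self, tmp_path, panel):
        path = tmp_path / "bad.csv"
        path.write_text(COHORT_CSV.replace("A/C,C/T", "A/Z,C/T"))
        with pytest.raises(CohortValidationError, match="S1.*rs1801131"):
            read_cohort(path, panel)

    def test_non_numeric_measurement_is_error(self, tmp_path, panel):
        path = tmp_path / "bad.csv"
        path.write_text(COHORT_CSV.replace("170", "tall"))
        with pytest.raises(CohortValidationError, match="non-numeric"):
            read_cohort(path, panel)

    def test_call_rate_report_at_study_missingness(self, panel):
        # 200 calls at one SNP with 13 blanked reproduces the assay's 93.5%
        entry = panel[0]
        records = [
            CohortRecord(
                sample_id=f"P{i}", sex="female", age=70.0,
                genotypes={
                    entry.snp_id: GenotypeCall.missing() if i < 13 else GenotypeCall("A", "C")
                },
            )
            for i in range(200)
        ]
        rates = call_rate_summary(records, [entry])
        assert rates.loc[0, "call_rate"] == pytest.approx(0.935)
        assert not rates.loc[0, "flagged"]

    def test_roundtrip_is_cell_identical(self, tmp_path, sim_spec, sim_cohort):
        records, _ = sim_cohort
        first, second = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(records, first, sim_spec.panel)
        reread = read_cohort(first, sim_spec.panel)
        write_cohort(reread, second, sim_spec.panel)
        assert first.read_bytes() == second.read_bytes()


class TestDosage:
    @pytest.mark.parametrize(
        "call, risk, expected",
        [
            (GenotypeCall("C", "C"), "C", 2),
            (GenotypeCall("A", "A"), "C", 0),
            (GenotypeCall("A", "C"), "C", 1),
            (GenotypeCall.missing(), "C", None),
        ],
    )
    def test_risk_allele_copy_count(self, call, risk, expected):
        assert genotype_dosage(call, risk) == expected

    def test_undetermined_risk_allele_is_error(self):
        with pytest.raises(ValueError, match="orient"):
            genotype_dosage(GenotypeCall("A", "C"), None)

    @pytest.mark.parametrize("a1, a2", [("A", "A"), ("A", "C"), ("C", "C")])
    def test_flipping_orientation_complements_to_two(self, a1, a2):
        call = GenotypeCall(a1, a2)
        assert genotype_dosage(call, "C") + genotype_dosage(call, "A") == 2


class TestGenotypeCounts:
    def test_explicit_tally(self, panel):
        entry = panel[0]  # risk allele C
        calls = [GenotypeCall("C", "C")] * 10 + [GenotypeCall("A", "C")] * 5 \
            + [GenotypeCall("A", "A")] * 5
        records = [
            CohortRecord(f"P{i}", "male", 70.0, genotypes={entry.snp_id: c})
            for i, c in enumerate(calls)
        ]
        counts = genotype_counts(records, entry.snp_id, entry)
        assert counts == GenotypeCounts(10, 5, 5)
        assert counts.n_risk_alleles == 25

    def test_group_counts_sum_to_total(self, sim_spec, sim_cohort):
        records, _ = sim_cohort
        for snp in sim_spec.snps:
            total = genotype_counts(records, snp.entry.snp_id, snp.entry)
            grouped = genotype_counts(records, snp.entry.snp_id, snp.entry, by_status=True)
            assert sum(grouped.values(), GenotypeCounts(0, 0, 0)) == total

    def test_zero_calls_is_error(self, panel):
        entry = panel[0]
        records = [CohortRecord("P0", "male", 70.0,
                                genotypes={entry.snp_id: GenotypeCall.missing()})]
        with pytest.raises(ValueError, match="zero non-missing"):
            genotype_counts(records, entry.snp_id, entry)


VCF_TEXT = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=1,length=249250621>\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
    "1\t100\trs1801131\tA\tC\t.\tPASS\t.\tGT\t0/1\t./.\t1|1\n"
)


class TestVcfImport:
    def test_gt_mapping_and_missing(self, tmp_path, panel):
        path = tmp_path / "in.vcf"
        path.write_text(VCF_TEXT)
        genotypes, warnings = import_vcf(path, panel)
        assert genotypes["S1"]["rs1801131"] == GenotypeCall("A", "C")
        assert genotypes["S2"]["rs1801131"].is_missing
        # phased 1|1 maps to the ALT homozygote, phase discarded
        assert genotypes["S3"]["rs1801131"] == GenotypeCall("C", "C")
        assert any("rs1815739" in w for w in warnings)

    def test_multiallelic_panel_snp_is_error(self, tmp_path, panel):
        path = tmp_path / "multi.vcf"
        path.write_text(VCF_TEXT.replace("\tC\t.\tPASS", "\tC,G\t.\tPASS"))
        with pytest.raises(CohortValidationError, match="biallelic"):
            import_vcf(path, panel)
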