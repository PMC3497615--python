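"""SNP reference, gene model and table I/O."""

import pandas as pd
import pytest

from imprintseq import (
    GeneRecord,
    SnpRecord,
    load_gene_models,
    load_snp_reference,
    map_snps_to_genes,
)
from imprintseq.snp_io import (
    ParseError,
    read_counts_table,
    read_predictions,
    write_counts_table,
    write_predictions,
)

from conftest import make_counts_frame


class TestSnpReferenceTsv:
    def test_field_mapping(self, snp_table):
        result = load_snp_reference(str(snp_table))
        rec = result.records[0]
        assert rec == SnpRecord("rs1", "chr1", 100, "+", "A", "G", 0.5)
        assert len(result) == 3

    def test_missing_frequency_dropped_and_counted(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text(
            "rs_id\tchrom\tposition\tstrand\tallele_x\tallele_y\tfreq_x\n"
            "rs1\tchr1\t100\t+\tA\tG\t0.5\n"
            "rs2\tchr1\t200\t+\tC\tT\tNA\n"
        )
        result = load_snp_reference(str(path))
        assert [r.rs_id for r in result] == ["rs1"]
        assert result.dropped_missing_freq == 1

    def test_frequency_out_of_range_raises(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text(
            "rs_id\tchrom\tposition\tstrand\tallele_x\tallele_y\tfreq_x\n"
            "rs1\tchr1\t100\t+\tA\tG\t1.5\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            load_snp_reference(str(path))

    def test_malformed_position_names_line(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text(
            "rs_id\tchrom\tposition\tstrand\tallele_x\tallele_y\tfreq_x\n"
            "rs1\tchr1\t100\t+\tA\tG\t0.5\n"
            "rs2\tchr1\toops\t+\tC\tT\t0.2\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            load_snp_reference(str(path))


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
    "##contig=<ID=chr1>\n##contig=<ID=chr2>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestSnpReferenceVcf:
    def test_multiallelic_record_dropped(self, tmp_path):
        path = tmp_path / "snps.vcf"
        path.write_text(
            VCF_HEADER
            + "chr1\t100\trs1\tA\tG\t.\t.\tAF=0.5\n"
            + "chr1\t200\trs2\tC\tT,G,A\t.\t.\tAF=0.1,0.1,0.1\n"
        )
        result = load_snp_reference(str(path))
        assert [r.rs_id for r in result] == ["rs1"]
        assert result.dropped_multiallelic == 1

    def test_vcf_and_tsv_agree_on_equivalent_content(self, tmp_path):
        vcf = tmp_path / "snps.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chr1\t100\trs1\tA\tG\t.\t.\tAF=0.5\n"
            + "chr2\t75\trs3\tC\tT\t.\t.\tAF=0.1\n"
        )
        tsv = tmp_path / "snps.tsv"
        tsv.write_text(
            "rs_id\tchrom\tposition\tstrand\tallele_x\tallele_y\tfreq_x\n"
            "rs1\tchr1\t100\t+\tA\tG\t0.5\n"
            "rs3\tchr2\t75\t+\tC\tT\t0.9\n"
        )
        from_vcf = {r for r in load_snp_reference(str(vcf))}
        from_tsv = {r for r in load_snp_reference(str(tsv))}
        assert from_vcf == from_tsv

    def test_missing_af_dropped(self, tmp_path):
        path = tmp_path / "snps.vcf"
        path.write_text(VCF_HEADER + "chr1\t100\trs1\tA\tG\t.\t.\t.\n")
        result = load_snp_reference(str(path))
        assert len(result) == 0
        assert result.dropped_missing_freq == 1


class TestSnpRecordInvariants:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            SnpRecord("rs1", "chr1", 1, "+", "A", "A", 0.5)

    def test_freq_y_derived(self, snp):
        assert snp.freq_y == pytest.approx(1 - snp.freq_x)

    def test_minor_allele_frequency(self):
        rec = SnpRecord("rs1", "chr1", 1, "+", "A", "G", 0.9)
        assert rec.minor_allele_frequency == pytest.approx(0.1)


def gene(gene_id, chrom, exons, strand="+"):
    return GeneRecord(gene_id=gene_id, symbol=gene_id, chrom=chrom, strand=strand,
                      exons=tuple(exons))


class TestGeneModels:
    def test_bed12_block_expansion(self, tmp_path):
        path = tmp_path / "genes.bed"
        # gene spanning 100-500 with exons [100,200) and [400,500)
        path.write_text(
            "chr1\t100\t500\tGENE1\t0\t+\t100\t500\t0\t2\t100,100\t0,300\n"
        )
        genes = load_gene_models(str(path))
        assert genes[0].exons == ((100, 200), (400, 500))

    def test_gtf_matches_bed12(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t500\tGENE1\t0\t+\t100\t500\t0\t2\t100,100\t0,300\n")
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GENE1"; transcript_id "T1";\n'
            'chr1\ttest\texon\t401\t500\t.\t+\t.\tgene_id "GENE1"; transcript_id "T1";\n'
        )
        assert load_gene_models(str(bed))[0].exons == load_gene_models(str(gtf))[0].exons

    def test_overlapping_exons_merged(self):
        g = gene("G", "chr1", [(10, 50), (40, 80), (100, 120)])
        assert g.exons == ((10, 80), (100, 120))

    def test_empty_exons_rejected(self):
        with pytest.raises(ValueError):
            gene("G", "chr1", [])


class TestSnpGeneMapping:
    def make_snp(self, rs_id, chrom, pos):
        return SnpRecord(rs_id, chrom, pos, "+", "A", "G", 0.5)

    def test_exonic_snp_assigned(self):
        snps = [self.make_snp("rs1", "chr1", 150)]
        genes = [gene("G1", "chr1", [(100, 200)])]
        assert list(map_snps_to_genes(snps, genes)) == [("rs1", "G1")]

    def test_snp_in_overlapping_genes_assigned_to_both(self):
        snps = [self.make_snp("rs1", "chr1", 150)]
        genes = [gene("G1", "chr1", [(100, 200)]), gene("G2", "chr1", [(120, 180)])]
        assert sorted(map_snps_to_genes(snps, genes)) == [("rs1", "G1"), ("rs1", "G2")]

    def test_intronic_snp_unassigned(self):
        snps = [self.make_snp("rs1", "chr1", 300)]
        genes = [gene("G1", "chr1", [(100, 200), (400, 500)])]
        assert len(map_snps_to_genes(snps, genes)) == 0

    def test_one_based_snp_vs_zero_based_exon_boundaries(self):
        genes = [gene("G1", "chr1", [(100, 200)])]
        # 1-based position 101 is the first base of the exon; 100 is just before it
        assert len(map_snps_to_genes([self.make_snp("rs1", "chr1", 101)], genes)) == 1
        assert len(map_snps_to_genes([self.make_snp("rs2", "chr1", 100)], genes)) == 0
        assert len(map_snps_to_genes([self.make_snp("rs3", "chr1", 200)], genes)) == 1
        assert len(map_snps_to_genes([self.make_snp("rs4", "chr1", 201)], genes)) == 0

    def test_order_independence(self):
        snps = [self.make_snp(f"rs{i}", "chr1", 100 + i * 30) for i in range(5)]
        genes = [gene("G1", "chr1", [(100, 180)]), gene("G2", "chr1", [(150, 400)])]
        fwd = map_snps_to_genes(snps, genes)
        rev = map_snps_to_genes(list(reversed(snps)), list(reversed(genes)))
        assert fwd.assignments == rev.assignments


class TestCountTables:
    def test_round_trip_identity(self, tmp_path):
        df = make_counts_frame(
            [("s1", "rs1", 5, 3, 0), ("s1", "rs2", 0, 9, 1), ("s2", "rs1", 7, 0, 2)]
        )
        path = tmp_path / "counts.tsv"
        write_counts_table(df, str(path))
        back = read_counts_table(str(path))
        pd.testing.assert_frame_equal(df, back)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "sample_id\trs_id\tcount_x\tcount_y\tcount_other\ns1\trs1\t-1\t3\t0\n"
        )
        with pytest.raises(ValueError, match="negative"):
            read_counts_table(str(path))

    def test_empty_file_yields_empty_frame(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("")
        assert len(read_counts_table(str(path))) == 0


class TestPredictionReports:
    def test_round_trip(self, tmp_path):
        rows = [
            {
                "rs_id": "rs1", "chrom": "chr1", "position": 100, "strand": "+",
                "posterior": 0.99, "gene_id": "G1", "symbol": "GENE1",
                "sample_size": 9, "fdr": 0.0,
            }
        ]
        path = tmp_path / "pred.tsv"
        write_predictions(rows, str(path))
        back = read_predictions(str(path))
        assert back.loc[0, "rs_id"] == "rs1"
        assert back.loc[0, "posterior"] == pytest.approx(0.99)
        assert list(back.columns)[:4] == ["rs_id", "chrom", "position", "strand"]
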