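"""Genotype, metadata and annotation I/O."""

import gzip

import numpy as np
import pytest

from introscan.genotype_io import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    ValidationError,
    read_gene_intervals,
    read_sample_metadata,
    read_vcf,
    write_vcf,
)

from conftest import make_random_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n"
)


def _write_vcf_text(path, body, samples=("a", "b", "c", "d")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    path.write_text(VCF_HEADER + cols + "\t" + "\t".join(samples) + "\n" + body)
    return path


class TestReadVcf:
    def test_gt_dosage_encoding(self, tmp_path):
        """0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. and half-calls -> MISSING; phase ignored."""
        body = "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n" \
               "chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t1|0\t./1\t1|1\t0/0\n"
        gm = read_vcf(_write_vcf_text(tmp_path / "x.vcf", body))
        assert gm.sample_ids == ("a", "b", "c", "d")
        assert gm.dosages[0].tolist() == [0, 1, 2, MISSING]
        assert gm.dosages[1].tolist() == [1, MISSING, 2, 0]

    def test_non_snp_records_dropped(self, tmp_path):
        """Indels and multiallelic records are filtered, SNPs kept."""
        body = (
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
            "chr1\t200\t.\tA\tATT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
            "chr1\t300\t.\tAC\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
            "chr1\t400\t.\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
        )
        gm = read_vcf(_write_vcf_text(tmp_path / "x.vcf", body))
        assert gm.n_sites == 1
        assert gm.pos.tolist() == [100]

    def test_duplicate_site_rejected(self, tmp_path):
        body = "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n" \
               "chr1\t100\t.\tC\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
        with pytest.raises(FormatError, match="duplicate"):
            read_vcf(_write_vcf_text(tmp_path / "x.vcf", body))

    def test_absent_sample_raises(self, tmp_path):
        body = "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
        path = _write_vcf_text(tmp_path / "x.vcf", body)
        with pytest.raises(LookupError):
            read_vcf(path, allowed_samples=["a", "nope"])
        gm = read_vcf(path, allowed_samples=["a", "c"])
        assert gm.sample_ids == ("a", "c")
        assert gm.dosages[0].tolist() == [0, 2]


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_write_read_identity(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        gm = make_random_matrix(rng, n_sites=rng.integers(1, 40), n_samples=rng.integers(1, 8))
        path = tmp_path / "rt.vcf"
        write_vcf(gm, path)
        assert read_vcf(path) == gm

    def test_column_sums_preserved(self, tmp_path, rng):
        gm = make_random_matrix(rng, 50, 6)
        write_vcf(gm, tmp_path / "rt.vcf")
        back = read_vcf(tmp_path / "rt.vcf")
        called = gm.dosages != MISSING
        np.testing.assert_array_equal(
            np.where(called, gm.dosages, 0).sum(axis=0),
            np.where(back.dosages != MISSING, back.dosages, 0).sum(axis=0),
        )

    def test_empty_matrix_header_only(self, tmp_path):
        gm = GenotypeMatrix(
            chrom=np.array([], dtype=object), pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object), alt=np.array([], dtype=object),
            dosages=np.empty((0, 3), dtype=np.int8), sample_ids=("a", "b", "c"),
        )
        path = tmp_path / "empty.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert back.n_sites == 0 and back.sample_ids == ("a", "b", "c")

    def test_gzip_roundtrip(self, tmp_path, rng):
        gm = make_random_matrix(rng, 20, 4)
        path = tmp_path / "rt.vcf.gz"
        write_vcf(gm, path)
        assert read_vcf(path) == gm


class TestMatrixInvariants:
    def test_bad_dosage_rejected(self, rng):
        gm = make_random_matrix(rng, 5, 3)
        gm.dosages[0, 0] = 7
        with pytest.raises(ValidationError):
            gm.validate()

    def test_unsorted_sites_rejected(self, rng):
        gm = make_random_matrix(rng, 5, 3)
        with pytest.raises(ValidationError):
            GenotypeMatrix(
                chrom=gm.chrom[::-1].copy(), pos=gm.pos[::-1].copy(),
                ref=gm.ref, alt=gm.alt, dosages=gm.dosages, sample_ids=gm.sample_ids,
            )


class TestSampleMetadata:
    def _write(self, path, rows):
        path.write_text(
            "sample_id\tspecies\tecotype\trole\n"
            + "".join("\t".join(r) + "\n" for r in rows)
        )
        return path

    def test_basic_parse(self, tmp_path):
        rows = [
            ("m1", "focal", "marine", "none"),
            ("f1", "focal", "freshwater", "none"),
            ("don", "donor", "NA", "p3_reference"),
            ("ref", "focal", "freshwater", "p1_reference"),
        ]
        ss = read_sample_metadata(self._write(tmp_path / "m.tsv", rows))
        assert ss.marine_ids == ("m1",)
        assert ss.freshwater_ids == ("f1", "ref")
        assert ss.p1_reference_id == "ref"
        assert ss.p3_reference_id == "don"

    def test_unknown_ecotype_rejected(self, tmp_path):
        rows = [("m1", "focal", "brackish", "none")]
        with pytest.raises(ValidationError, match="brackish"):
            read_sample_metadata(self._write(tmp_path / "m.tsv", rows))

    @pytest.mark.parametrize(
        "rows, match",
        [
            ([("a", "focal", "marine", "none"), ("a", "focal", "marine", "none")], "duplicate"),
            ([("a", "focal", "NA", "p1_reference"), ("b", "focal", "NA", "p1_reference")],
             "p1_reference"),
            ([("a", "donor", "marine", "none")], "focal"),
        ],
    )
    def test_validation_errors(self, tmp_path, rows, match):
        with pytest.raises(ValidationError, match=match):
            read_sample_metadata(self._write(tmp_path / "m.tsv", rows))

    def test_cohort_scale_group_sizes(self, tmp_path):
        """A 271-marine / 599-freshwater cohort parses to those group sizes."""
        rows = [(f"m{i}", "focal", "marine", "none") for i in range(271)]
        rows += [(f"f{i}", "focal", "freshwater", "none") for i in range(599)]
        ss = read_sample_metadata(self._write(tmp_path / "big.tsv", rows))
        assert (len(ss.marine_ids), len(ss.freshwater_ids)) == (271, 599)

    def test_gzip_metadata(self, tmp_path):
        text = "sample_id\tspecies\tecotype\trole\nm1\tfocal\tmarine\tnone\n"
        path = tmp_path / "m.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(text)
        assert read_sample_metadata(path).marine_ids == ("m1",)


GFF3 = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=mrnaA;Parent=geneA
chr1\tsrc\texon\t101\t150\t.\t+\t.\tParent=mrnaA
"""


class TestGeneIntervals:
    def test_bed_identity_convention(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t100\t200\tgeneA\n")
        ann = read_gene_intervals(path, format="bed")
        assert ann.intervals == (("chr1", 100, 200, ".", "geneA"),)

    def test_gff3_conversion_matches_bed(self, tmp_path):
        """A GFF3 gene at 101..200 equals the BED interval [100, 200)."""
        gff = tmp_path / "g.gff3"
        gff.write_text(GFF3)
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t100\t200\tgeneA\t0\t+\n")
        a_gff = read_gene_intervals(gff, format="gff3")
        a_bed = read_gene_intervals(bed, format="bed")
        assert [(c, s, e) for c, s, e, *_ in a_gff.intervals] == [
            (c, s, e) for c, s, e, *_ in a_bed.intervals
        ]
        assert a_gff.intervals[0][4] == "geneA"

    def test_gff3_non_gene_features_ignored(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=mrnaA\n"
            "chr1\tsrc\texon\t101\t150\t.\t+\t.\tID=exon1;Parent=mrnaA\n"
        )
        assert len(read_gene_intervals(gff, format="gff3")) == 0

    def test_bad_interval_rejected(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t200\t100\tgeneA\n")
        with pytest.raises(FormatError):
            read_gene_intervals(bed, format="bed")
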