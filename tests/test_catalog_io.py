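"""Catalog parsing, VCF dosage coding and the strict missing-data filter."""

import numpy as np
import pandas as pd
import pytest

from neanderscore import (
    MISSING,
    CatalogError,
    GenotypeMatrix,
    SnpCatalog,
    SnpRecord,
    drop_incomplete_snps,
    genotypes_from_vcf,
    parse_locus,
    read_snp_catalog,
    write_vcf,
)

CATALOG_TSV = (
    "chrom\tpos\tancestral\tarchaic\trsid\teurope_specific\n"
    "1\t1000\tA\tG\trs1\ttrue\n"
    "1\t2000\tC\tT\trs2\ttrue\n"
    "2\t500\tG\tA\trs3\ttrue\n"
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestCatalogReading:
    def test_well_formed_rows_preserved_in_order(self, tmp_path):
        cat = read_snp_catalog(write(tmp_path, "c.tsv", CATALOG_TSV))
        assert cat.rsids == ["rs1", "rs2", "rs3"]
        assert cat[0].archaic_allele == "G"

    def test_duplicate_rsid_rejected_with_name(self, tmp_path):
        bad = CATALOG_TSV + "3\t1\tA\tC\trs1\ttrue\n"
        with pytest.raises(CatalogError, match="rs1"):
            read_snp_catalog(write(tmp_path, "c.tsv", bad))

    def test_duplicate_coordinate_triple_rejected(self):
        with pytest.raises(CatalogError, match="triple"):
            SnpCatalog(
                [SnpRecord("1", 10, "A", "G", "rsA"), SnpRecord("1", 10, "C", "G", "rsB")]
            )

    def test_europe_specific_filter(self, tmp_path):
        rows = CATALOG_TSV + "3\t1\tA\tC\trs4\tfalse\n3\t2\tA\tC\trs5\tfalse\n"
        p = write(tmp_path, "c.tsv", rows)
        assert len(read_snp_catalog(p)) == 3
        assert len(read_snp_catalog(p, europe_specific_only=False)) == 5

    @pytest.mark.parametrize(
        "rec",
        [
            dict(chrom="1", pos=0, ancestral_allele="A", archaic_allele="G", rsid="x"),
            dict(chrom="1", pos=5, ancestral_allele="AT", archaic_allele="G", rsid="x"),
            dict(chrom="1", pos=5, ancestral_allele="A", archaic_allele="A", rsid="x"),
        ],
    )
    def test_invalid_records_rejected(self, rec):
        with pytest.raises(CatalogError):
            SnpRecord(**rec)

    def test_locus_string_roundtrip(self):
        rec = parse_locus("10:132208002:G>A", rsid="rs79220014")
        assert (rec.chrom, rec.pos) == ("10", 132208002)
        assert rec.ancestral_allele == "G" and rec.archaic_allele == "A"
        assert rec.locus == "10:132208002:G>A"


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n##contig=<ID=2>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


class TestVcfDosages:
    def vcf(self, tmp_path, body):
        return write(tmp_path, "g.vcf", VCF_HEADER + body)

    def test_dosage_codes_het_hom_missing(self, tmp_path, tiny_catalog):
        body = (
            "1\t1000\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t./.\n"
            "1\t2000\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t1|0\t1/1\n"
        )
        m = genotypes_from_vcf(self.vcf(tmp_path, body), tiny_catalog)
        assert m.to_frame().loc["s1", "rs1"] == 1  # heterozygous archaic
        assert m.to_frame().loc["s2", "rs1"] == 2  # homozygous archaic
        assert m.to_frame().loc["s3", "rs1"] == MISSING
        # phased separator treated as unphased
        assert list(m.to_frame()["rs2"]) == [0, 1, 2]

    def test_swapped_orientation_complements_dosage(self, tmp_path, tiny_catalog):
        # REF carries the archaic allele: 0/0 means two archaic copies
        body = "1\t1000\trs1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        m = genotypes_from_vcf(self.vcf(tmp_path, body), tiny_catalog)
        assert list(m.to_frame()["rs1"]) == [2, 1, 0]

    def test_absent_snps_missing_and_logged(self, tmp_path, tiny_catalog):
        body = "1\t1000\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\n"
        m = genotypes_from_vcf(self.vcf(tmp_path, body), tiny_catalog)
        absent = m.removal_log.query("reason == 'absent_from_vcf'")["rsid"]
        assert set(absent) == {"rs2", "rs3", "rs4", "rs5"}
        assert (m.to_frame()["rs2"] == MISSING).all()

    def test_allele_mismatch_warns_and_codes_missing(self, tmp_path, tiny_catalog):
        body = "1\t1000\trs1\tA\tC\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\n"
        m = genotypes_from_vcf(self.vcf(tmp_path, body), tiny_catalog)
        assert (m.to_frame()["rs1"] == MISSING).all()
        assert "allele_mismatch" in set(m.removal_log["reason"])

    def test_indel_rejected(self, tmp_path, tiny_catalog):
        body = "1\t1000\trs1\tA\tGT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        with pytest.raises(CatalogError, match="SNV"):
            genotypes_from_vcf(self.vcf(tmp_path, body), tiny_catalog)

    def test_multiallelic_decomposed_when_archaic_present(self, tmp_path, tiny_catalog):
        body = "1\t1000\trs1\tA\tG,C\t.\tPASS\t.\tGT\t0/1\t1/1\t0/2\n"
        m = genotypes_from_vcf(self.vcf(tmp_path, body), tiny_catalog)
        # carriers of the non-matching ALT cannot be coded biallelically
        assert list(m.to_frame()["rs1"]) == [1, 2, MISSING]

    def test_multiple_files_stack_samples(self, tmp_path, tiny_catalog):
        body = "1\t1000\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\n"
        p1 = write(tmp_path, "a.vcf", VCF_HEADER + body)
        header2 = VCF_HEADER.replace("s1\ts2\ts3", "t1\tt2\tt3")
        p2 = write(tmp_path, "b.vcf", header2 + body)
        m = genotypes_from_vcf([p1, p2], tiny_catalog)
        assert m.sample_ids == ["s1", "s2", "s3", "t1", "t2", "t3"]


class TestMissingDataFilter:
    def test_snps_with_any_missing_removed(self, tiny_catalog):
        dosage = np.zeros((3, 5), dtype=np.int8)
        dosage[0, 1] = MISSING
        dosage[2, 3] = MISSING
        m = GenotypeMatrix(["a", "b", "c"], tiny_catalog, dosage)
        kept, removed = drop_incomplete_snps(m)
        assert kept.snps.rsids == ["rs1", "rs3", "rs5"]
        assert [r.rsid for r in removed] == ["rs2", "rs4"]
        assert not kept.missing_mask().any()
        assert set(kept.removal_log.query("reason == 'missing_call'")["rsid"]) == {
            "rs2", "rs4"
        }

    def test_no_missing_is_identity_and_idempotent(self, tiny_catalog):
        m = GenotypeMatrix(["a"], tiny_catalog, np.ones((1, 5), dtype=np.int8))
        kept, removed = drop_incomplete_snps(m)
        assert removed == [] and kept.n_snps == 5
        kept2, removed2 = drop_incomplete_snps(kept)
        assert removed2 == [] and np.array_equal(kept2.dosage, kept.dosage)

    def test_counts_partition(self, tiny_catalog):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
        dosage[rng.random((10, 5)) < 0.05] = MISSING
        m = GenotypeMatrix([f"s{i}" for i in range(10)], tiny_catalog, dosage)
        kept, removed = drop_incomplete_snps(m)
        assert kept.n_snps + len(removed) == 5

    def test_all_removed_raises(self, tiny_catalog):
        m = GenotypeMatrix(
            ["a"], tiny_catalog, np.full((1, 5), MISSING, dtype=np.int8)
        )
        with pytest.raises(CatalogError, match="incompatible"):
            drop_incomplete_snps(m)


class TestRoundTripAndComplement:
    def test_vcf_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(11)
        from neanderscore import synthetic_catalog

        cat = synthetic_catalog(30, rng)
        dosage = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        dosage[rng.random((8, 30)) < 0.1] = MISSING
        m = GenotypeMatrix([f"s{i}" for i in range(8)], cat, dosage)
        path = tmp_path / "rt.vcf"
        write_vcf(m, path)
        m2 = genotypes_from_vcf(path, cat)
        assert m2.sample_ids == m.sample_ids
        assert np.array_equal(m2.dosage, m.dosage)

    def test_orientation_swap_complements_every_call(self, tmp_path, tiny_catalog):
        rng = np.random.default_rng(7)
        dosage = rng.integers(0, 3, size=(6, 5)).astype(np.int8)
        dosage[0, 0] = MISSING
        m = GenotypeMatrix([f"s{i}" for i in range(6)], tiny_catalog, dosage)
        path = tmp_path / "fwd.vcf"
        write_vcf(m, path)
        # swap REF/ALT and GT coding on every record -> same archaic dosage
        lines = path.read_text().splitlines()
        swapped = []
        for line in lines:
            if line.startswith("#"):
                swapped.append(line)
                continue
            f = line.split("\t")
            f[3], f[4] = f[4], f[3]
            f[9:] = [
                {"0/0": "1/1", "0/1": "1/0", "1/1": "0/0", "./.": "./."}[g]
                for g in f[9:]
            ]
            swapped.append("\t".join(f))
        path2 = tmp_path / "swapped.vcf"
        path2.write_text("\n".join(swapped) + "\n")
        m2 = genotypes_from_vcf(path2, tiny_catalog)
        assert np.array_equal(m2.dosage, m.dosage)
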