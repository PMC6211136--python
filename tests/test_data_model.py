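"""Readers, containers, and the three SNP binary encodings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logicforest.data_model import (
    GenotypeMatrix,
    ParseError,
    PhenotypeTable,
    assemble_dataset,
    encode_snp,
    read_genotypes,
    read_phenotypes,
    write_genotypes_tsv,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestGenotypeTSV:
    def test_basic_parse(self, tmp_path):
        path = write(tmp_path, "g.tsv", "subject_id\trs1\nA\t0\nB\t2\n")
        gm = read_genotypes(path, "tsv")
        assert gm.subject_ids == ["A", "B"]
        assert gm.snp_ids == ["rs1"]
        assert gm.dosage[:, 0].tolist() == [0.0, 2.0]

    def test_malformed_value_names_line(self, tmp_path):
        path = write(tmp_path, "g.tsv", "subject_id\trs1\nA\t0\nB\t7\n")
        with pytest.raises(ParseError, match=":3"):
            read_genotypes(path, "tsv")

    def test_missing_is_na(self, tmp_path):
        path = write(tmp_path, "g.tsv", "subject_id\trs1\trs2\nA\tNA\t1\n")
        gm = read_genotypes(path, "tsv")
        assert np.isnan(gm.dosage[0, 0]) and gm.dosage[0, 1] == 1

    def test_round_trip(self, tmp_path, rng):
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(7, 5))
        gm = GenotypeMatrix([f"s{i}" for i in range(7)],
                            [f"rs{j}" for j in range(5)], dosage)
        out = tmp_path / "rt.tsv"
        write_genotypes_tsv(gm, out)
        gm2 = read_genotypes(str(out), "tsv")
        assert gm2.subject_ids == gm.subject_ids
        assert gm2.snp_ids == gm.snp_ids
        np.testing.assert_array_equal(np.isnan(gm.dosage), np.isnan(gm2.dosage))
        np.testing.assert_array_equal(gm.dosage[~np.isnan(gm.dosage)],
                                      gm2.dosage[~np.isnan(gm2.dosage)])


class TestPlinkRaw:
    def test_parse_and_allele_suffix(self, tmp_path):
        path = write(
            tmp_path, "g.raw",
            "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_T\n"
            "F1 A 0 0 1 2 0 1\nF2 B 0 0 2 1 2 NA\n",
        )
        gm = read_genotypes(path, "plink_raw")
        assert gm.subject_ids == ["A", "B"]
        assert gm.snp_ids == ["rs1", "rs2"]
        assert gm.allele_labels["rs1"][0] == "A"
        assert np.isnan(gm.dosage[1, 1])

    def test_bad_header(self, tmp_path):
        path = write(tmp_path, "g.raw", "IID FID rs1\nA F1 0\n")
        with pytest.raises(ParseError):
            read_genotypes(path, "plink_raw")


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


class TestVCF:
    def test_alt_is_minor(self, tmp_path):
        path = write(tmp_path, "v.vcf",
                     VCF_HEADER + "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        gm = read_genotypes(path, "vcf")
        # ALT frequency 3/6 = 0.5 tie -> oriented toward ALT
        assert gm.dosage[:, 0].tolist() == [0.0, 1.0, 2.0]

    def test_ref_is_minor_recounts(self, tmp_path):
        # ALT frequency 5/6 -> minor allele is REF; hom-ALT maps to dosage 0
        path = write(tmp_path, "v.vcf",
                     VCF_HEADER + "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t1/1\t1/1\t0/1\n")
        gm = read_genotypes(path, "vcf")
        assert gm.dosage[:, 0].tolist() == [0.0, 0.0, 1.0]
        assert gm.allele_labels["rs1"] == ("A", "G")

    def test_multiallelic_rejected(self, tmp_path):
        path = write(tmp_path, "v.vcf",
                     VCF_HEADER + "1\t200\trs2\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t2/2\n")
        with pytest.raises(ParseError, match="1:200"):
            read_genotypes(path, "vcf")

    def test_positions_recorded(self, tmp_path):
        path = write(tmp_path, "v.vcf",
                     VCF_HEADER + "7\t5432\trs9\tC\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/1\n")
        gm = read_genotypes(path, "vcf")
        assert gm.positions["rs9"] == ("7", 5432)


class TestPhenotypes:
    def test_basic(self, tmp_path):
        path = write(tmp_path, "p.tsv",
                     "subject_id\tstatus\tpsc\nA\t1\t1\nB\t0\t0\nC\t1\tNA\n")
        ph = read_phenotypes(path)
        assert ph.status.tolist() == [1, 0, 1]
        assert np.isnan(ph.exposures["psc"].iloc[2])

    def test_missing_status_column(self, tmp_path):
        path = write(tmp_path, "p.tsv", "subject_id\tpsc\nA\t1\n")
        with pytest.raises(ParseError, match="status"):
            read_phenotypes(path)

    def test_bad_status_value(self, tmp_path):
        path = write(tmp_path, "p.tsv", "subject_id\tstatus\nA\t2\n")
        with pytest.raises(ParseError):
            read_phenotypes(path)

    def test_duplicate_subject_id(self, tmp_path):
        path = write(tmp_path, "p.tsv", "subject_id\tstatus\nA\t1\nA\t0\n")
        with pytest.raises(ValueError, match="A"):
            read_phenotypes(path)

    def test_non_binary_exposure_becomes_missing(self, tmp_path):
        path = write(tmp_path, "p.tsv", "subject_id\tstatus\tpsc\nA\t1\t3\n")
        ph = read_phenotypes(path)
        assert np.isnan(ph.exposures["psc"].iloc[0])


class TestEncoding:
    @pytest.mark.parametrize(
        "scheme,expected",
        [
            ("recessive", [[0, 0, 1]]),
            ("dominant", [[0, 1, 1]]),
            ("genotypic", [[0, 1, 0], [0, 0, 1]]),
        ],
    )
    def test_schemes(self, scheme, expected):
        cols = encode_snp(np.array([0.0, 1.0, 2.0]), scheme, "rs1")
        assert [c.tolist() for c, _ in cols] == [[float(v) for v in e] for e in expected]

    def test_missing_propagates(self):
        (col, _), = encode_snp(np.array([np.nan, 2.0]), "recessive", "rs1")
        assert np.isnan(col[0]) and col[1] == 1

    def test_recessive_complement_rendering(self):
        (_, desc), = encode_snp(np.array([0.0]), "recessive", "rs77")
        assert "major allele" in desc.render(complemented=True)
        assert "rs77" in desc.render(complemented=True)

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_encoding_identities(self, dosages):
        d = np.array(dosages, dtype=float)
        (rec, _), = encode_snp(d, "recessive")
        (dom, _), = encode_snp(d, "dominant")
        (g1, _), (g2, _) = encode_snp(d, "genotypic")
        assert (rec <= dom).all()
        np.testing.assert_array_equal(g1 + g2, dom)
        # complement of recessive == indicator of >=1 copy of the major allele
        np.testing.assert_array_equal(1 - rec, (d <= 1).astype(float))


class TestAssemble:
    def _gm(self):
        return GenotypeMatrix(
            ["A", "B", "C", "D", "E"], ["rs1"],
            np.array([[0.0], [1.0], [2.0], [np.nan], [0.0]]),
        )

    def _ph(self):
        import pandas as pd

        return PhenotypeTable(
            ["A", "B", "C", "D", "E"], np.array([1, 0, 1, 0, 1]),
            pd.DataFrame({"psc": [1.0, 0.0, 1.0, 1.0, np.nan]}),
        )

    def test_listwise_deletion(self):
        W = assemble_dataset(self._gm(), self._ph(), "recessive", ["psc"])
        assert W.n == 3  # D missing genotype, E missing psc
        assert W.subject_ids == ["A", "B", "C"]
        assert W.p == 2

    def test_empty_overlap_errors(self):
        gm = self._gm()
        gm = GenotypeMatrix(["X", "Y", "Z", "W", "V"], gm.snp_ids, gm.dosage)
        with pytest.raises(ValueError, match="overlap"):
            assemble_dataset(gm, self._ph(), "recessive", ["psc"])

    def test_148_snps_plus_5_exposures_gives_153(self, rng):
        import pandas as pd

        n, m = 30, 148
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n)], [f"rs{j}" for j in range(m)],
            rng.choice([0.0, 1.0, 2.0], size=(n, m)),
        )
        expo = pd.DataFrame({k: rng.integers(0, 2, n).astype(float)
                             for k in ["psc", "psa", "ever", "current", "female"]})
        ph = PhenotypeTable([f"s{i}" for i in range(n)], rng.integers(0, 2, n), expo)
        W = assemble_dataset(gm, ph, "recessive")
        assert W.p == 153

    def test_descriptor_alignment(self):
        W = assemble_dataset(self._gm(), self._ph(), "genotypic", ["psc"])
        assert [d.name for d in W.descriptors] == ["rs1_G1", "rs1_G2", "psc"]
        assert W.descriptors[0].source_snp == "rs1"
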