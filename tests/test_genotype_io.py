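"""Genotype I/O: EIGENSTRAT/VCF parsing, round trips, allele counting."""

import numpy as np
import pandas as pd
import pytest

from admixscan.genotype_io import (
    MISSING,
    AlleleCounts,
    ConfigurationError,
    GenotypeFormatError,
    PopulationMap,
    compute_counts,
    read_eigenstrat,
    read_population_map,
    read_vcf,
    write_eigenstrat,
    write_population_map,
    write_vcf,
)


def _write_triplet(prefix, geno_lines, snp_lines, ind_lines):
    with open(f"{prefix}.geno", "w") as fh:
        fh.write("\n".join(geno_lines) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        fh.write("\n".join(snp_lines) + "\n")
    with open(f"{prefix}.ind", "w") as fh:
        fh.write("\n".join(ind_lines) + "\n")


SNP2 = ["rs1\t1\t0\t100\tA\tG", "rs2\t2\t0\t200\tC\tT"]
IND3 = ["i1\tM\tP1", "i2\tF\tP1", "i3\tU\tP2"]


class TestEigenstrat:
    def test_parses_codes_and_missing(self, tmp_path):
        prefix = tmp_path / "d"
        _write_triplet(prefix, ["029", "910"], SNP2, IND3)
        gm = read_eigenstrat(prefix)
        assert gm.codes[0, 2] == MISSING and gm.codes[1, 0] == MISSING
        assert gm.codes[0, 0] == 0 and gm.codes[0, 1] == 2 and gm.codes[1, 1] == 1
        # i2 carries a het -> diploid; i1/i3 inferred pseudohaploid
        assert list(gm.ploidy) == [1, 2, 1]

    def test_all_missing_individual_contributes_nothing(self, tmp_path):
        prefix = tmp_path / "d"
        _write_triplet(prefix, ["029", "919"], SNP2, IND3)
        gm = read_eigenstrat(prefix)
        counts = compute_counts(gm, {"i1": "P1", "i2": "P1", "i3": "P2"})
        assert counts.n_ind["P2"].tolist() == [0, 0]
        assert counts.n_alleles["P2"].tolist() == [0, 0]
        assert np.isnan(counts.freq("P2")).all()

    def test_dimension_mismatch_names_offender(self, tmp_path):
        prefix = tmp_path / "d"
        _write_triplet(prefix, ["029", "91"], SNP2, IND3)
        with pytest.raises(GenotypeFormatError, match="line 2"):
            read_eigenstrat(prefix)
        _write_triplet(prefix, ["029"], SNP2, IND3)
        with pytest.raises(GenotypeFormatError, match="1 rows"):
            read_eigenstrat(prefix)

    def test_non_digit_character_names_site(self, tmp_path):
        prefix = tmp_path / "d"
        _write_triplet(prefix, ["029", "9x0"], SNP2, IND3)
        with pytest.raises(GenotypeFormatError, match="site index 1"):
            read_eigenstrat(prefix)

    def test_invalid_code_rejected(self, tmp_path):
        prefix = tmp_path / "d"
        _write_triplet(prefix, ["029", "930"], SNP2, IND3)
        with pytest.raises(GenotypeFormatError, match="not in 0/1/2/9"):
            read_eigenstrat(prefix)

    def test_write_read_roundtrip_byte_identical(self, tmp_path, small_dataset):
        gm, _, _, _ = small_dataset
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_eigenstrat(gm, p1)
        write_eigenstrat(read_eigenstrat(p1), p2)
        for ext in (".geno", ".snp", ".ind"):
            assert (p1.parent / f"a{ext}").read_bytes() == (p2.parent / f"b{ext}").read_bytes()

    def test_ref_polarity_flips_codes(self, tmp_path, small_dataset):
        gm, _, _, _ = small_dataset
        prefix = tmp_path / "d"
        write_eigenstrat(gm, prefix, counted_allele="REF")
        back = read_eigenstrat(prefix, counted_allele="REF")
        assert np.array_equal(back.codes, gm.codes)
        flipped = read_eigenstrat(prefix)  # misread polarity: ALT copies complement
        obs = gm.codes != MISSING
        assert np.array_equal(flipped.codes[obs], 2 - gm.codes[obs])


class TestVcf:
    def test_encodings(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t1\t./.\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1/1\t0\t.\n"
        )
        gm = read_vcf(vcf)
        assert gm.codes[0].tolist() == [1, 2, MISSING]
        assert gm.codes[1].tolist() == [2, 0, MISSING]
        assert list(gm.ploidy) == [2, 1, 1]

    def test_multiallelic_skipped_by_default(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t1/2\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1/1\n"
        )
        gm = read_vcf(vcf)
        assert gm.n_sites == 1 and gm.snp["snp_id"].iloc[0] == "rs2"
        with pytest.raises(GenotypeFormatError, match="multi-allelic"):
            read_vcf(vcf, multiallelic="error")

    def test_vcf_roundtrip_identity(self, tmp_path, small_dataset):
        gm, _, _, _ = small_dataset
        path = tmp_path / "cohort.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert np.array_equal(back.codes, gm.codes)
        assert list(back.ploidy) == list(gm.ploidy)
        assert back.snp["pos"].tolist() == gm.snp["pos"].tolist()

    def test_cross_format_count_equivalence(self, tmp_path, small_dataset):
        """The same cohort exported to EIGENSTRAT and VCF yields identical counts."""
        gm, pm, counts, _ = small_dataset
        write_eigenstrat(gm, tmp_path / "e")
        write_vcf(gm, tmp_path / "v.vcf")
        gm_e = read_eigenstrat(tmp_path / "e")
        gm_v = read_vcf(tmp_path / "v.vcf")
        gm_v.ind["population"] = gm.ind["population"].to_numpy()
        for other in (compute_counts(gm_e, pm), compute_counts(gm_v, pm)):
            for pop in counts.populations:
                assert np.array_equal(other.x[pop], counts.x[pop])
                assert np.array_equal(other.n_alleles[pop], counts.n_alleles[pop])
                assert np.array_equal(other.n_ind[pop], counts.n_ind[pop])


class TestCounts:
    def test_pseudohaploid_arithmetic(self):
        """Five pseudohaploid individuals {2,2,0,2,MISSING}: x=3 of n=4."""
        from admixscan.genotype_io import GenotypeMatrix

        snp = pd.DataFrame(
            [["rs1", "1", 0.0, 100, "A", "G"]],
            columns=["snp_id", "chrom", "gpos", "pos", "ref", "alt"],
        )
        ind = pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(5)],
                "sex": "U",
                "population": "P",
            }
        )
        codes = np.array([[2, 2, 0, 2, MISSING]], dtype=np.int8)
        gm = GenotypeMatrix(snp, ind, codes, np.ones(5, dtype=np.int8))
        counts = compute_counts(gm, {f"i{k}": "P" for k in range(5)})
        assert counts.x["P"][0] == 3
        assert counts.n_alleles["P"][0] == 4
        assert counts.n_ind["P"][0] == 4
        assert counts.freq("P")[0] == pytest.approx(0.75)

    def test_count_conservation_under_pooling(self, small_dataset):
        _, _, counts, _ = small_dataset
        pooled = counts.pool(["target", "source1"], "EF")
        assert np.array_equal(pooled.x["EF"], counts.x["target"] + counts.x["source1"])
        assert np.array_equal(
            pooled.n_alleles["EF"], counts.n_alleles["target"] + counts.n_alleles["source1"]
        )

    def test_frequency_within_binomial_interval(self):
        """200 pseudohaploid individuals at true ALT frequency 0.3."""
        from scipy import stats

        from admixscan.calibration import generate_synthetic_dataset, SimulationConfig

        cfg = SimulationConfig(
            n_null_sites=1,
            n_selected_sites=0,
            source_freq_model=("uniform", 0.3, 0.3000001),
            admixture_gamma=1.0,
            sample_sizes=(200, 200, 200),
            seed=11,
        )
        _, _, counts, _ = generate_synthetic_dataset(cfg)
        lo, hi = stats.binom.interval(0.99, 200, 0.3)
        assert lo <= counts.x["source1"][0] <= hi

    def test_counts_tsv_roundtrip(self, tmp_path, small_dataset):
        _, _, counts, _ = small_dataset
        path = tmp_path / "counts.tsv"
        counts.to_tsv(path)
        back = AlleleCounts.from_tsv(path)
        assert back.roles == counts.roles
        for pop in counts.populations:
            assert np.array_equal(back.x[pop], counts.x[pop])
            assert np.array_equal(back.n_alleles[pop], counts.n_alleles[pop])

    def test_empty_population_is_configuration_error(self, tiny_matrix):
        pm = PopulationMap("P1", "P2", "P3", {"i1": "P1", "i2": "P1", "i3": "P2"})
        with pytest.raises(ConfigurationError, match="P3"):
            compute_counts(tiny_matrix, pm)

    def test_unknown_individual_rejected(self, tiny_matrix):
        with pytest.raises(ConfigurationError, match="ghost"):
            compute_counts(tiny_matrix, {"ghost": "P3", "i1": "P1", "i3": "P2"})


class TestPopulationMap:
    def test_roles_must_be_distinct(self):
        with pytest.raises(ConfigurationError):
            PopulationMap("A", "A", "B")

    def test_tsv_roundtrip(self, tmp_path):
        pm = PopulationMap("LBK", "Anatolia_N", "WHG", {"d1": "LBK", "b8": "Anatolia_N", "lo": "WHG"})
        path = tmp_path / "pops.tsv"
        write_population_map(pm, path)
        back = read_population_map(path)
        assert back.roles == pm.roles and back.assignments == pm.assignments

    def test_missing_role_header_rejected(self, tmp_path):
        path = tmp_path / "pops.tsv"
        path.write_text("#target=LBK\n#source1=Anatolia_N\nd1\tLBK\n")
        with pytest.raises(ConfigurationError, match="source2"):
            read_population_map(path)
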