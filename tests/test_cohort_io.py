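"""Cohort containers, HAPS/SAMPLE and VCF parsing, and QC filters."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from haplogic.cohort import (MISSING, PhasedCohort, Variant, hwe_exact_p,
                             qc_filter, split_cohort)
from haplogic.io import read_haps_sample, read_phased_vcf, write_haps_sample

from conftest import make_cohort


class TestContainers:
    def test_row_pairing_and_genotypes(self):
        haps = np.array([[0, 1], [1, 1], [0, 0], [1, 0]])
        c = make_cohort(haps, [1, 0])
        g = c.genotypes()
        assert g.tolist() == [[1, 2], [1, 0]]

    def test_missing_genotype_propagates(self):
        haps = np.array([[0], [MISSING], [1], [1]])
        g = make_cohort(haps, [0, 1]).genotypes()
        assert g.tolist() == [[MISSING], [2]]

    def test_rejects_bad_allele_codes(self):
        with pytest.raises(ValueError, match="0, 1 or -1"):
            make_cohort(np.array([[2], [0]]), [1])

    def test_rejects_odd_rows(self):
        variants = [Variant("rs0", "1", 100)]
        with pytest.raises(ValueError, match="2 per subject"):
            PhasedCohort(variants, np.zeros((3, 1), dtype=np.int8),
                         pd.DataFrame({"subject_id": ["a"], "phenotype": [0]}))


class TestSplit:
    def test_split_by_label(self):
        labels = ["discovery"] * 10 + ["replication"] * 5
        c = make_cohort(np.zeros((30, 2)), [0, 1] * 7 + [0], labels)
        assert split_cohort(c, "replication").n_subjects == 5
        assert split_cohort(c, "discovery").n_subjects == 10
        assert split_cohort(c, "combined").n_subjects == 15
        with pytest.raises(ValueError, match="no subjects"):
            split_cohort(c, "validation")


def _hwe_brute(n_hom_ref, n_het, n_hom_alt):
    """Exact-fraction enumeration of the conditional het-count distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    probs = {}
    for het in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        hom_alt = (n_alt - het) // 2
        hom_ref = n - het - hom_alt
        if hom_ref < 0 or hom_alt < 0:
            continue
        w = Fraction(2 ** het,
                     math.factorial(hom_ref) * math.factorial(het)
                     * math.factorial(hom_alt))
        probs[het] = w
    tot = sum(probs.values())
    obs = probs[n_het] / tot
    return float(sum(p for p in (v / tot for v in probs.values())
                     if p <= obs))


class TestHwe:
    @pytest.mark.parametrize("counts", [(21, 18, 11), (50, 20, 5),
                                        (5, 5, 5), (100, 10, 30), (0, 3, 7)])
    def test_matches_exact_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(_hwe_brute(*counts),
                                                     rel=1e-10)

    def test_equilibrium_counts_give_p_one(self):
        assert hwe_exact_p(1, 2, 1) == 1.0

    def test_extreme_departure_small_p(self):
        # all-heterozygote with many subjects is wildly off equilibrium
        assert hwe_exact_p(0, 50, 0) < 1e-6


class TestQc:
    def _cohort(self, rng, n=100, m=5):
        haps = (rng.random((2 * n, m)) < 0.3).astype(np.int8)
        y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
        return haps, y

    def test_monomorphic_removed_under_maf(self, rng):
        haps, y = self._cohort(rng)
        haps[:, 2] = 0
        out, rep = qc_filter(make_cohort(haps, y))
        assert rep.removed_maf >= 1
        assert "rs2" in rep.dropped_variant_ids

    def test_low_call_rate_removed(self, rng):
        haps, y = self._cohort(rng)
        miss = rng.choice(haps.shape[0], size=haps.shape[0] // 10,
                          replace=False)
        haps[miss, 1] = MISSING  # 10% missing entries -> 0.90 < 0.95
        out, rep = qc_filter(make_cohort(haps, y))
        assert "rs1" in rep.dropped_variant_ids
        assert rep.removed_call_rate >= 1

    def test_hwe_filter_uses_controls(self, rng):
        haps, y = self._cohort(rng, n=200)
        # make SNP 0 all-heterozygous in controls only
        controls = np.flatnonzero(y == 0)
        for i in controls:
            haps[2 * i, 0] = 0
            haps[2 * i + 1, 0] = 1
        out, rep = qc_filter(make_cohort(haps, y))
        assert "rs0" in rep.dropped_variant_ids
        assert rep.removed_hwe >= 1

    def test_counts_balance_and_idempotence(self, rng):
        haps, y = self._cohort(rng, n=150, m=8)
        haps[:, 0] = 0
        haps[rng.choice(300, 40, replace=False), 3] = MISSING
        c = make_cohort(haps, y)
        out, rep = qc_filter(c)
        assert rep.n_variants_in - rep.n_variants_out == (
            rep.removed_call_rate + rep.removed_maf + rep.removed_hwe)
        assert rep.n_subjects_in - rep.n_subjects_out == rep.removed_sample_call
        out2, rep2 = qc_filter(out)
        assert rep2.n_variants_out == out.n_variants
        assert out2.n_variants == out.n_variants
        assert out2.n_subjects == out.n_subjects

    def test_all_removed_raises(self):
        haps = np.zeros((20, 2), dtype=np.int8)
        with pytest.raises(ValueError, match="all variants removed"):
            qc_filter(make_cohort(haps, [0, 1] * 5))


class TestHapsSample:
    def test_parse_columns_map_to_chromosomes(self, tmp_path):
        haps = tmp_path / "x.haps"
        haps.write_text("1 rs1 100 A G 0 1 1 0\n"
                        "1 rs2 200 C T 1 1 0 0\n"
                        "1 rs3 300 G A 0 0 0 1\n")
        sample = tmp_path / "x.sample"
        sample.write_text("ID_1 ID_2 missing pheno\n0 0 0 B\n"
                          "a a 0 1\nb b 0 0\n")
        c = read_haps_sample(str(haps), str(sample))
        assert c.haps[:, 0].tolist() == [0, 1, 1, 0]
        assert c.haps.T.tolist() == [[0, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 1]]
        assert c.subjects["phenotype"].tolist() == [1, 0]

    def test_non_biallelic_token_rejected(self, tmp_path):
        haps = tmp_path / "x.haps"
        haps.write_text("1 rs1 100 A G 0 2 1 0\n")
        sample = tmp_path / "x.sample"
        sample.write_text("ID_1 ID_2 missing pheno\n0 0 0 B\na a 0 1\nb b 0 0\n")
        with pytest.raises(ValueError, match="non-biallelic"):
            read_haps_sample(str(haps), str(sample))

    def test_subject_count_mismatch_rejected(self, tmp_path):
        haps = tmp_path / "x.haps"
        haps.write_text("1 rs1 100 A G 0 1 1 0\n")
        sample = tmp_path / "x.sample"
        sample.write_text("ID_1 ID_2 missing pheno\n0 0 0 B\na a 0 1\n")
        with pytest.raises(ValueError, match="haplotype columns"):
            read_haps_sample(str(haps), str(sample))

    def test_round_trip_byte_identical(self, tmp_path, rng):
        haps = (rng.random((10, 4)) < 0.4).astype(np.int8)
        haps[3, 2] = MISSING
        c = make_cohort(haps, [1, 0, 0, 1, 0])
        write_haps_sample(c, tmp_path / "a.haps", tmp_path / "a.sample")
        c2 = read_haps_sample(str(tmp_path / "a.haps"),
                              str(tmp_path / "a.sample"))
        assert np.array_equal(c.haps, c2.haps)
        write_haps_sample(c2, tmp_path / "b.haps", tmp_path / "b.sample")
        assert (tmp_path / "a.haps").read_text() == \
            (tmp_path / "b.haps").read_text()
        assert (tmp_path / "a.sample").read_text() == \
            (tmp_path / "b.sample").read_text()


VCF_HEADER = ('##fileformat=VCFv4.2\n##contig=<ID=1>\n'
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
              '#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n')


class TestPhasedVcf:
    def _write(self, tmp_path, body):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_HEADER + body)
        phen = tmp_path / "ph.tsv"
        phen.write_text("S1\t1\nS2\t0\n")
        return str(path), str(phen)

    def test_phased_gt_maps_to_rows(self, tmp_path):
        vcf, phen = self._write(
            tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t1|0\t0|1\n")
        c = read_phased_vcf(vcf, phenotype_path=phen)
        assert c.haps[:, 0].tolist() == [1, 0, 0, 1]

    def test_missing_components(self, tmp_path):
        vcf, phen = self._write(
            tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t.|.\t1|1\n")
        c = read_phased_vcf(vcf, phenotype_path=phen)
        assert c.haps[:, 0].tolist() == [MISSING, MISSING, 1, 1]

    def test_unphased_separator_rejected(self, tmp_path):
        vcf, phen = self._write(
            tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\n")
        with pytest.raises(ValueError, match="unphased"):
            read_phased_vcf(vcf, phenotype_path=phen)

    def test_vcf_round_trip(self, tmp_path, rng):
        from haplogic.io import write_phased_vcf

        haps = (rng.random((8, 3)) < 0.4).astype(np.int8)
        haps[2, 1] = MISSING
        haps[3, 1] = MISSING
        c = make_cohort(haps, [1, 0, 1, 0])
        path = tmp_path / "rt.vcf"
        write_phased_vcf(c, str(path))
        phen = tmp_path / "ph.tsv"
        phen.write_text("".join(f"S{i}\t{p}\n" for i, p in
                                enumerate([1, 0, 1, 0])))
        c2 = read_phased_vcf(str(path), phenotype_path=str(phen))
        assert np.array_equal(c.haps, c2.haps)
        assert [v.id for v in c2.variants] == [v.id for v in c.variants]
        path2 = tmp_path / "rt2.vcf"
        write_phased_vcf(c2, str(path2))
        assert path.read_text() == path2.read_text()
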