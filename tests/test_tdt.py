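import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cleftminer import (
    BedInterval,
    SignificanceTiers,
    TransmissionCounts,
    TrioPanel,
    TrioTDT,
    UninformativeSNP,
    assign_genes,
    count_transmissions,
    read_trios,
    tdt_statistic,
)
from cleftminer.errors import FormatError, LookupFailure
from cleftminer.tdt import SNP


def make_panel(trio_dosages, snp=None):
    """Panel with one SNP; trio_dosages = [(father, mother, child) allele-B dosage]."""
    snp = snp or SNP("rs1", "1", 100, "A", "B")
    geno = np.array([[[f], [m], [c]] for f, m, c in trio_dosages], dtype=np.int8)
    return TrioPanel([snp], geno)


class TestCountTransmissions:
    def test_single_het_father_transmits_a(self):
        # father AB, mother AA, child AA: father transmitted A
        panel = make_panel([(1, 0, 0)])
        assert count_transmissions(panel, "rs1") == TransmissionCounts(1, 0)

    def test_het_by_het_het_child_is_one_of_each(self):
        panel = make_panel([(1, 1, 1)])
        assert count_transmissions(panel, "rs1") == TransmissionCounts(1, 1)

    def test_het_by_het_homozygous_children(self):
        assert count_transmissions(make_panel([(1, 1, 0)]), "rs1") == (
            TransmissionCounts(2, 0)
        )
        assert count_transmissions(make_panel([(1, 1, 2)]), "rs1") == (
            TransmissionCounts(0, 2)
        )

    def test_no_heterozygous_parent_contributes_nothing(self):
        # father AA, mother BB, child AB
        panel = make_panel([(0, 2, 1)])
        assert count_transmissions(panel, "rs1") == TransmissionCounts(0, 0)

    def test_mendelian_error_trio_excluded(self):
        # father AA, mother AB, child BB is impossible: excluded entirely
        panel = make_panel([(0, 1, 2), (1, 0, 0)])
        assert count_transmissions(panel, "rs1") == TransmissionCounts(1, 0)

    def test_missing_child_genotype_skipped(self):
        panel = make_panel([(1, 0, -1), (1, 0, 1)])
        assert count_transmissions(panel, "rs1") == TransmissionCounts(0, 1)

    def test_unknown_snp(self):
        with pytest.raises(LookupFailure):
            count_transmissions(make_panel([(1, 0, 0)]), "nope")


class TestTDTStatistic:
    def test_null_symmetry(self):
        chi2, p = tdt_statistic(TransmissionCounts(10, 10))
        assert chi2 == 0.0 and p == 1.0

    def test_distorted_counts(self):
        chi2, p = tdt_statistic(TransmissionCounts(20, 5))
        assert chi2 == pytest.approx(9.0)
        assert p == pytest.approx(0.0026998, rel=1e-4)

    def test_single_transmission(self):
        chi2, p = tdt_statistic(TransmissionCounts(1, 0))
        assert chi2 == pytest.approx(1.0)
        assert p == pytest.approx(0.3173105, rel=1e-6)

    def test_uninformative(self):
        with pytest.raises(UninformativeSNP):
            tdt_statistic(TransmissionCounts(0, 0))

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=300, deadline=None)
    def test_matches_mcnemar_normal_tail(self, b, c):
        """chi2(1) upper tail equals the two-sided normal tail of (b-c)/sqrt(b+c)."""
        if b + c == 0:
            return
        chi2, p = tdt_statistic(TransmissionCounts(b, c))
        z = abs(b - c) / np.sqrt(b + c)
        assert p == pytest.approx(2 * norm.sf(z), rel=1e-9)
        # allele-label swap leaves the statistic unchanged
        chi2_swap, p_swap = tdt_statistic(TransmissionCounts(c, b))
        assert chi2 == chi2_swap and p == p_swap


class TestAssignGenes:
    SNPS = [SNP("rs1", "1", 100, "A", "B"), SNP("rs2", "2", 100, "A", "B")]

    def test_boundary_inclusion_exclusion(self):
        # 1-based position 100 is 0-based point 99
        inside = [BedInterval("1", 99, 100, "GIN")]
        outside = [BedInterval("1", 100, 200, "GOUT")]
        assert assign_genes(self.SNPS, inside)["rs1"] == {"GIN"}
        assert assign_genes(self.SNPS, outside)["rs1"] == set()

    def test_chromosome_must_match(self):
        iv = [BedInterval("1", 0, 1000, "G")]
        assert assign_genes(self.SNPS, iv)["rs2"] == set()

    def test_flank_monotone(self):
        iv = [BedInterval("1", 500, 600, "G")]
        base = assign_genes(self.SNPS, iv, flank_bp=0)
        wide = assign_genes(self.SNPS, iv, flank_bp=1000)
        for snp_id in base:
            assert base[snp_id] <= wide[snp_id]
        assert wide["rs1"] == {"G"}

    def test_bad_bed(self, tmp_path):
        from cleftminer import read_bed

        bad = tmp_path / "bad.bed"
        bad.write_text("1\t10\n")
        with pytest.raises(FormatError, match="bad.bed:1"):
            read_bed(bad)


class TestReadTrios:
    def _write(self, tmp_path, ped_text, map_text="1 rs1 0 100\n"):
        ped = tmp_path / "t.ped"
        mp = tmp_path / "t.map"
        ped.write_text(ped_text)
        mp.write_text(map_text)
        return ped, mp

    def test_one_trio_one_snp(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            "f1 dad 0 0 1 2 A B\n"
            "f1 mom 0 0 2 2 A A\n"
            "f1 kid dad mom 1 2 A A\n",
        )
        panel = read_trios(ped, mp)
        assert panel.n_trios == 1 and panel.n_snps == 1
        assert count_transmissions(panel, "rs1") == TransmissionCounts(1, 0)

    def test_singletons_only_warns(self, tmp_path):
        ped, mp = self._write(
            tmp_path, "f1 a 0 0 1 2 A A\nf2 b 0 0 2 2 A B\n"
        )
        with pytest.warns(UserWarning, match="no complete trios"):
            panel = read_trios(ped, mp)
        assert panel.n_trios == 0

    def test_absent_parent_excluded(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            "f1 mom 0 0 2 2 A A\n"
            "f1 kid ghost mom 1 2 A A\n",
        )
        with pytest.warns(UserWarning):
            panel = read_trios(ped, mp)
        assert panel.n_trios == 0

    def test_column_mismatch(self, tmp_path):
        ped, mp = self._write(tmp_path, "f1 a 0 0 1 2 A\n")
        with pytest.raises(FormatError, match="columns"):
            read_trios(ped, mp)

    def test_multiallelic_rejected(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            "f1 dad 0 0 1 2 A B A A\n"
            "f1 mom 0 0 2 2 C C A B\n"
            "f1 kid dad mom 1 2 A C A B\n",
            "1 rs1 0 100\n1 rs2 0 200\n",
        )
        with pytest.warns(UserWarning, match="multiallelic"):
            panel = read_trios(ped, mp)
        assert [s.snp_id for s in panel.snps] == ["rs2"]


class TestScan:
    def test_tier_labels(self):
        tiers = SignificanceTiers(alpha=0.05)
        assert tiers.label(1e-9, 179) == "genome_wide"
        assert tiers.label(1e-6, 179) == "gene_wide"
        assert tiers.label(1e-4, 179) == "candidate_wise"
        assert tiers.label(1e-3, 179) == "ns"
        assert tiers.candidate_wise(179) == pytest.approx(2.79e-4, rel=5e-3)

    def test_snp_without_gene_absent_from_gene_table(self):
        panel = make_panel([(1, 0, 0), (1, 1, 1)])
        res = TrioTDT(panel, gene_map={}).fit()
        assert len(res.snp_results) == 1
        assert res.gene_table.empty
        assert res.n_genes == 0 and res.candidate_threshold is None

    def test_gene_table_top_marker(self):
        snps = [SNP("rs1", "1", 100, "A", "B"), SNP("rs2", "1", 200, "A", "B")]
        # rs1 strongly distorted, rs2 balanced
        geno = np.zeros((20, 3, 2), dtype=np.int8)
        geno[:, 0, 0] = 1   # father het at rs1
        geno[:, 2, 0] = 0   # child got A -> b = 20
        geno[:10, 0, 1] = 1
        geno[:10, 2, 1] = 0
        geno[10:, 0, 1] = 1
        geno[10:, 2, 1] = 1  # 10 A, 10 B at rs2
        panel = TrioPanel(snps, geno)
        res = TrioTDT(panel, {"rs1": {"GENE"}, "rs2": {"GENE"}}).fit()
        gt = res.gene_table
        assert list(gt["gene"]) == ["GENE"]
        assert gt.loc[0, "top_marker"] == "rs1"
        assert gt.loc[0, "b"] == 20 and gt.loc[0, "c"] == 0

    def test_summary_mentions_counts(self):
        panel = make_panel([(1, 0, 0)])
        text = TrioTDT(panel, {"rs1": {"G"}}).fit().summary()
        assert "genes tested         1" in text
        assert "informative SNPs     1" in text
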