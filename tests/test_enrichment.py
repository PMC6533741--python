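import numpy as np
import pytest

from cleftminer import (
    EmptyInputError,
    FamilyMap,
    GeneSet,
    GeneSetEnrichment,
    MiRNAEnrichment,
    SyntheticSpec,
    count_families_per_gene,
    fisher_exact_one_sided,
    geneset_enrichment,
    mirna_enrichment,
    read_gmt,
    simulate_target_universe,
    write_gmt,
)
from cleftminer.datasets import (
    load_family_map,
    load_published_enrichment_rows,
    load_published_target_map,
)
from cleftminer.enrichment import UNKNOWN_FAMILY


class TestMiRNAEnrichment:
    def test_planted_mirna_ranks_first(self):
        spec = SyntheticSpec(
            seed=7, n_genes_universe=600, n_foreground=60, n_mirnas=30,
            target_size_range=(15, 30), planted_mirnas=1, enrichment_odds=10.0,
        )
        tmap, foreground, truth = simulate_target_universe(spec)
        res = MiRNAEnrichment(tmap, foreground).fit(fdr_threshold=0.1)
        (planted,) = [m for m, v in truth.items() if v]
        assert res.rows[0].mirna == planted  # smallest q after (q, p, id) sort
        # rerun with the same seed gives the identical result table
        tmap2, fg2, _ = simulate_target_universe(spec)
        res2 = MiRNAEnrichment(tmap2, fg2).fit(fdr_threshold=0.1)
        assert res.table.equals(res2.table)

    def test_foreground_equal_universe_degenerate(self, tiny_target_map):
        res = MiRNAEnrichment(tiny_target_map, tiny_target_map.universe).fit()
        for row in res.rows:
            assert row.k == row.n
            assert row.p == 1.0
        assert res.significant == []

    def test_empty_intersection_raises(self, tiny_target_map):
        with pytest.raises(EmptyInputError):
            MiRNAEnrichment(tiny_target_map, {"NOT_A_GENE"})

    def test_counts_and_bh_family(self, tiny_target_map):
        rows = mirna_enrichment(
            tiny_target_map, {"G1", "G2"}, FamilyMap({"miR-a": "famA"})
        )
        by_id = {r.mirna: r for r in rows}
        assert by_id["miR-a"].k == 2 and by_id["miR-a"].n == 3
        assert by_id["miR-b"].k == 1
        assert by_id["miR-c"].k == 0 and by_id["miR-c"].p == 1.0
        assert by_id["miR-a"].family == "famA"
        assert by_id["miR-b"].family == UNKNOWN_FAMILY
        # BH is applied across all tested miRNAs (m = 3 here)
        m = len(rows)
        assert all(r.q <= 1 for r in rows)
        sorted_p = sorted(r.p for r in rows)
        assert min(r.q for r in rows) == pytest.approx(
            min(p * m / (i + 1) for i, p in enumerate(sorted_p))
        )

    def test_type_one_error_control_under_null(self):
        """With no planted enrichment, few runs produce any q < 0.1 hit."""
        n_runs = 200
        false_runs = 0
        for seed in range(n_runs):
            spec = SyntheticSpec(
                seed=seed, n_genes_universe=800, n_foreground=60, n_mirnas=25,
                target_size_range=(15, 35), planted_mirnas=0,
            )
            tmap, fg, _ = simulate_target_universe(spec)
            rows = mirna_enrichment(tmap, fg, fdr_threshold=0.1)
            if any(r.significant for r in rows):
                false_runs += 1
        assert false_runs / n_runs <= 0.15


class TestFamilyCounts:
    def test_published_rollup_members(self):
        rows = load_published_enrichment_rows()
        counts = {c.gene: c for c in count_families_per_gene(rows)}
        assert counts["EN2"].n_families == 6
        assert counts["EN2"].families == {
            "miR-154", "miR-203", "miR-27", "miR-368", "miR-374", "miR-497"
        }
        # the unknown-family miRNA never contributes a family
        assert counts["YOD1"].n_families == 5
        assert "NA" not in counts["YOD1"].families
        assert UNKNOWN_FAMILY not in counts["YOD1"].families

    def test_single_mirna(self, tiny_target_map):
        rows = mirna_enrichment(
            tiny_target_map, {"G1", "G2"}, FamilyMap({"miR-a": "famA"})
        )
        only_a = [r for r in rows if r.mirna == "miR-a"]
        counts = count_families_per_gene(only_a)
        assert all(c.n_families == 1 for c in counts if c.gene in {"G1", "G2"})
        only_b = [r for r in rows if r.mirna == "miR-b"]  # UNKNOWN family
        assert all(c.n_families == 0 for c in count_families_per_gene(only_b))

    def test_permutation_invariance(self):
        rows = load_published_enrichment_rows()
        fwd = count_families_per_gene(rows)
        rev = count_families_per_gene(list(reversed(rows)))
        assert fwd == rev

    def test_empty_rows_raise(self):
        with pytest.raises(EmptyInputError):
            count_families_per_gene([])


class TestGeneSetEnrichment:
    UNIVERSE = [f"G{i}" for i in range(20)]
    FOREGROUND = [f"G{i}" for i in range(5)]

    def test_agrees_exactly_with_fisher(self):
        term = GeneSet("T1", "d", frozenset(["G0", "G1", "G2", "G10"]))  # k=3, n=4
        rows = geneset_enrichment(
            self.FOREGROUND, [term], self.UNIVERSE, min_overlap=0,
        )
        assert rows[0].p == fisher_exact_one_sided(3, 5, 4, 20)
        assert rows[0].p == pytest.approx(155 / 4845)

    def test_min_overlap_filter_applied_before_testing(self):
        t_small = GeneSet("small", "d", frozenset(["G0", "G10"]))  # overlap 1
        t_big = GeneSet("big", "d", frozenset(self.FOREGROUND))
        rows = geneset_enrichment(
            self.FOREGROUND, [t_small, t_big], self.UNIVERSE, min_overlap=4
        )
        assert [r.mirna for r in rows] == ["big"]
        # BH m must be the number of *tested* terms (1), so q == p
        assert rows[0].q == rows[0].p

    def test_term_equal_foreground_is_minimal_p(self):
        terms = [
            GeneSet("exact", "d", frozenset(self.FOREGROUND)),
            GeneSet("off", "d", frozenset(["G0", "G1", "G2", "G3", "G10"])),
        ]
        rows = geneset_enrichment(
            self.FOREGROUND, terms, self.UNIVERSE, min_overlap=0
        )
        assert rows[0].mirna == "exact"
        assert rows[0].p == min(r.p for r in rows)

    def test_universe_must_cover_foreground(self):
        with pytest.raises(ValueError):
            GeneSetEnrichment(["X1"], [GeneSet("t", "d", frozenset(["G1"]))], ["G1"])

    def test_empty_collection_raises(self):
        with pytest.raises(EmptyInputError):
            GeneSetEnrichment(self.FOREGROUND, [], self.UNIVERSE)

    def test_gmt_roundtrip(self, tmp_path):
        sets = [
            GeneSet("T1", "first term", frozenset(["G1", "G2", "G3"])),
            GeneSet("T2", "second", frozenset(["G2", "G4"])),
        ]
        path = tmp_path / "anno.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert back == sets


def test_published_table_structure():
    tmap = load_published_target_map()
    fam = load_family_map()
    families = {fam.family(m) for m in tmap.mirnas}
    assert len(tmap) == 16
    assert UNKNOWN_FAMILY in families
    assert len(families - {UNKNOWN_FAMILY}) == 10
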