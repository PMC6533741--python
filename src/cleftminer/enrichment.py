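"""Gene-set enrichment models.

Two statsmodels-style models live here:

:class:`MiRNAEnrichment`
    For every miRNA in a :class:`~cleftminer.targets.TargetMap`, test whether
    its target set is enriched for a foreground (candidate) gene set with a
    one-sided Fisher's exact test, control the FDR across all tested miRNAs
    with Benjamini-Hochberg, and aggregate significant miRNAs into seed
    families to count how many distinct families target each gene.

:class:`GeneSetEnrichment`
    Generic hypergeometric over-representation of a foreground set in GMT
    annotation terms (GO/KEGG/HPO-style), with a minimum-overlap filter
    applied before testing and BH FDR across the tested terms.

The two share one 2x2 statistic (:func:`cleftminer.stats.fisher_exact_one_sided`)
so their p-values agree exactly on identical tables.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import normalize_symbol
from .errors import EmptyInputError, FormatError
from .stats import bh_fdr, fisher_exact_one_sided
from .targets import TargetMap

__all__ = [
    "UNKNOWN_FAMILY",
    "FamilyMap",
    "EnrichmentRow",
    "GeneFamilyCount",
    "MiRNAEnrichment",
    "MiRNAEnrichmentResults",
    "mirna_enrichment",
    "count_families_per_gene",
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "GeneSetEnrichment",
    "geneset_enrichment",
]

#: Family id used for miRNAs absent from the family map (or mapped to "NA").
UNKNOWN_FAMILY = "UNKNOWN"


class FamilyMap:
    """miRNA -> seed-family id; unmapped miRNAs resolve to :data:`UNKNOWN_FAMILY`.

    Matching is case-insensitive on the miRNA id.  Family ids equal to
    ``"NA"`` (any case) or empty are treated as unknown.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        for mirna, family in (mapping or {}).items():
            fam = str(family).strip()
            if not fam or fam.upper() == "NA":
                fam = UNKNOWN_FAMILY
            self._map[mirna.strip().lower()] = fam

    def family(self, mirna: str) -> str:
        return self._map.get(mirna.strip().lower(), UNKNOWN_FAMILY)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyMap":
        """Read a two-column TSV (``mirna``, ``family``); '#' comments allowed."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        if not {"mirna", "family"} <= set(df.columns):
            raise FormatError(f"{path}: need columns mirna, family")
        return cls(dict(zip(df["mirna"], df["family"])))


@dataclass(frozen=True)
class EnrichmentRow:
    """One enrichment test: a 2x2 overlap table with its p- and q-value.

    ``k`` genes of the ``n``-gene target/term set fall in the ``K``-gene
    foreground, inside a universe of ``N`` genes.
    """

    mirna: str
    family: str
    overlap_genes: frozenset[str]
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    significant: bool = False

    def __post_init__(self) -> None:
        if self.k != len(self.overlap_genes):
            raise ValueError(
                f"{self.mirna}: k={self.k} but {len(self.overlap_genes)} overlap genes"
            )


@dataclass(frozen=True)
class GeneFamilyCount:
    """How many distinct known miRNA families hit one gene."""

    gene: str
    n_families: int
    families: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_families != len(self.families):
            raise ValueError(f"{self.gene}: family count/set mismatch")


def _rows_to_frame(rows: Sequence[EnrichmentRow], id_col: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                id_col: r.mirna,
                "family": r.family,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
                "overlap_genes": ",".join(sorted(r.overlap_genes)),
            }
            for r in rows
        ],
        columns=[id_col, "family", "k", "K", "n", "N", "p", "q", "significant",
                 "overlap_genes"],
    )


class MiRNAEnrichmentResults:
    """Fitted per-miRNA enrichment: rows, significant subset, family rollup."""

    def __init__(
        self,
        rows: list[EnrichmentRow],
        fdr_threshold: float,
        model: "MiRNAEnrichment",
    ) -> None:
        self.rows = rows
        self.fdr_threshold = fdr_threshold
        self.model = model

    @property
    def significant(self) -> list[EnrichmentRow]:
        return [r for r in self.rows if r.significant]

    @property
    def table(self) -> pd.DataFrame:
        return _rows_to_frame(self.rows, "mirna")

    def family_counts(self, min_families: int = 2) -> list[GeneFamilyCount]:
        """Genes targeted by at least ``min_families`` distinct known families
        among the significant miRNAs."""
        counts = count_families_per_gene(self.significant)
        return [c for c in counts if c.n_families >= min_families]

    def family_table(self, min_families: int = 2) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": c.gene,
                    "n_families": c.n_families,
                    "families": ",".join(sorted(c.families)),
                }
                for c in self.family_counts(min_families)
            ],
            columns=["gene", "n_families", "families"],
        )

    def summary(self) -> str:
        sig = self.significant
        fams = {r.family for r in sig if r.family != UNKNOWN_FAMILY}
        unknown = sum(1 for r in sig if r.family == UNKNOWN_FAMILY)
        lines = [
            "miRNA target-set enrichment (one-sided Fisher, BH FDR)",
            "=" * 56,
            f"universe size N          {self.rows[0].N if self.rows else 0}",
            f"foreground size K        {self.rows[0].K if self.rows else 0}",
            f"miRNAs tested            {len(self.rows)}",
            f"significant (q < {self.fdr_threshold:g})    {len(sig)}",
            f"known families hit       {len(fams)}"
            + (f" (+{unknown} unknown-family miRNA(s))" if unknown else ""),
        ]
        if sig:
            lines.append("-" * 56)
            lines.append(f"{'miRNA':<22}{'family':<10}{'k':>4}{'n':>5}{'q':>10}")
            for r in sig:
                lines.append(
                    f"{r.mirna:<22}{r.family:<10}{r.k:>4}{r.n:>5}{r.q:>10.3g}"
                )
        return "\n".join(lines)


class MiRNAEnrichment:
    """Per-miRNA Fisher enrichment of a foreground gene set in target sets.

    Parameters
    ----------
    target_map : TargetMap
        Per-miRNA target sets and the background universe.
    foreground : iterable of str
        Candidate gene symbols (normalized internally); only the part inside
        the universe enters the 2x2 tables.
    family_map : FamilyMap, optional
        miRNA -> seed-family assignment used for the family rollup.

    Examples
    --------
    >>> res = MiRNAEnrichment(tmap, catalog.symbol_set()).fit(fdr_threshold=0.1)
    >>> res.table.head()          # doctest: +SKIP
    """

    def __init__(
        self,
        target_map: TargetMap,
        foreground: Iterable[str],
        family_map: FamilyMap | None = None,
    ) -> None:
        self.target_map = target_map
        self.foreground = frozenset(normalize_symbol(g) for g in foreground)
        self.family_map = family_map or FamilyMap()
        self.foreground_in_universe = self.foreground & target_map.universe
        if not self.foreground_in_universe:
            raise EmptyInputError(
                "foreground does not intersect the target-map universe"
            )

    def fit(self, fdr_threshold: float = 0.1) -> MiRNAEnrichmentResults:
        if not (0 < fdr_threshold <= 1):
            raise ValueError("fdr_threshold must lie in (0, 1]")
        K = len(self.foreground_in_universe)
        N = len(self.target_map.universe)
        mirnas = self.target_map.mirnas
        raw = []
        for m in mirnas:
            targets = self.target_map.targets[m]
            overlap = frozenset(targets & self.foreground_in_universe)
            n = len(targets)
            k = len(overlap)
            raw.append((m, overlap, k, n, fisher_exact_one_sided(k, K, n, N)))
        qs = bh_fdr([r[4] for r in raw])
        rows = [
            EnrichmentRow(
                mirna=m,
                family=self.family_map.family(m),
                overlap_genes=overlap,
                k=k,
                K=K,
                n=n,
                N=N,
                p=p,
                q=q,
                significant=q < fdr_threshold,
            )
            for (m, overlap, k, n, p), q in zip(raw, qs)
        ]
        rows.sort(key=lambda r: (r.q, r.p, r.mirna))
        return MiRNAEnrichmentResults(rows, fdr_threshold, self)


def mirna_enrichment(
    target_map: TargetMap,
    foreground: Iterable[str],
    family_map: FamilyMap | None = None,
    fdr_threshold: float = 0.1,
) -> list[EnrichmentRow]:
    """Functional wrapper: fit :class:`MiRNAEnrichment` and return its rows."""
    return MiRNAEnrichment(target_map, foreground, family_map).fit(fdr_threshold).rows


def count_families_per_gene(rows: Sequence[EnrichmentRow]) -> list[GeneFamilyCount]:
    """Distinct known miRNA families hitting each gene in the given rows.

    ``rows`` is normally the significant subset of an enrichment fit.  For
    every gene in any row's overlap set, count the distinct families (the
    :data:`UNKNOWN_FAMILY` sentinel is excluded) of the miRNAs whose overlap
    contains the gene.  Sorted by descending count, then symbol.
    """
    if not rows:
        raise EmptyInputError("no enrichment rows to aggregate")
    fams: dict[str, set[str]] = defaultdict(set)
    for row in rows:
        for gene in row.overlap_genes:
            fams.setdefault(gene, set())
            if row.family != UNKNOWN_FAMILY:
                fams[gene].add(row.family)
    out = [
        GeneFamilyCount(gene=g, n_families=len(fs), families=frozenset(fs))
        for g, fs in fams.items()
    ]
    out.sort(key=lambda c: (-c.n_families, c.gene))
    return out


# ---------------------------------------------------------------------------
# Generic GMT-based over-representation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """One GMT annotation term."""

    term: str
    description: str
    genes: frozenset[str]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: per line ``term<TAB>description<TAB>gene...``."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        genes = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
        if not genes:
            raise FormatError(f"{path}:{lineno}: term {parts[0]!r} has no genes")
        sets.append(GeneSet(parts[0], parts[1], genes))
    if not sets:
        raise EmptyInputError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term, s.description, *sorted(s.genes)]) + "\n")


class GeneSetEnrichment:
    """Hypergeometric over-representation of a foreground in annotation terms.

    Terms whose foreground overlap is below ``min_overlap`` are removed
    *before* testing, so they do not enter the BH correction.  The default
    ``min_overlap=4`` suits KEGG/GO-style runs; phenotype-ontology runs
    conventionally use 5.
    """

    def __init__(
        self,
        foreground: Iterable[str],
        annotation_sets: Sequence[GeneSet],
        universe: Iterable[str],
    ) -> None:
        if not annotation_sets:
            raise EmptyInputError("empty annotation collection")
        self.universe = frozenset(normalize_symbol(g) for g in universe)
        self.foreground = frozenset(normalize_symbol(g) for g in foreground)
        if not self.foreground <= self.universe:
            raise ValueError("universe must contain the foreground")
        self.annotation_sets = list(annotation_sets)

    def fit(
        self, min_overlap: int = 4, fdr_threshold: float = 0.05
    ) -> "GeneSetEnrichmentResults":
        if min_overlap < 0:
            raise ValueError("min_overlap must be >= 0")
        N = len(self.universe)
        K = len(self.foreground)
        tested = []
        for s in self.annotation_sets:
            term_genes = s.genes & self.universe
            if not term_genes:
                continue
            overlap = frozenset(term_genes & self.foreground)
            if len(overlap) < min_overlap:
                continue
            p = fisher_exact_one_sided(len(overlap), K, len(term_genes), N)
            tested.append((s, overlap, len(term_genes), p))
        rows: list[EnrichmentRow] = []
        if tested:
            qs = bh_fdr([t[3] for t in tested])
            rows = [
                EnrichmentRow(
                    mirna=s.term,
                    family=s.description,
                    overlap_genes=overlap,
                    k=len(overlap),
                    K=K,
                    n=n,
                    N=N,
                    p=p,
                    q=q,
                    significant=q < fdr_threshold,
                )
                for (s, overlap, n, p), q in zip(tested, qs)
            ]
            rows.sort(key=lambda r: (r.q, r.p, r.mirna))
        return GeneSetEnrichmentResults(rows, fdr_threshold, self)


class GeneSetEnrichmentResults:
    """Fitted term enrichment; ``table`` uses a ``term`` id column."""

    def __init__(
        self,
        rows: list[EnrichmentRow],
        fdr_threshold: float,
        model: GeneSetEnrichment,
    ) -> None:
        self.rows = rows
        self.fdr_threshold = fdr_threshold
        self.model = model

    @property
    def significant(self) -> list[EnrichmentRow]:
        return [r for r in self.rows if r.significant]

    @property
    def table(self) -> pd.DataFrame:
        df = _rows_to_frame(self.rows, "term")
        return df.rename(columns={"family": "description"})

    def summary(self) -> str:
        lines = [
            "gene-set over-representation (hypergeometric, BH FDR)",
            "=" * 54,
            f"terms tested             {len(self.rows)}",
            f"significant (q < {self.fdr_threshold:g})   {len(self.significant)}",
        ]
        for r in self.significant:
            lines.append(f"  {r.mirna:<30} k={r.k:<4} q={r.q:.3g}")
        return "\n".join(lines)


def geneset_enrichment(
    foreground: Iterable[str],
    annotation_sets: Sequence[GeneSet],
    universe: Iterable[str],
    min_overlap: int = 4,
    fdr_threshold: float = 0.05,
) -> list[EnrichmentRow]:
    """Functional wrapper over :class:`GeneSetEnrichment`."""
    model = GeneSetEnrichment(foreground, annotation_sets, universe)
    return model.fit(min_overlap=min_overlap, fdr_threshold=fdr_threshold).rows
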