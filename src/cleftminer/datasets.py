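"""Loaders for the small data tables shipped with the package.

Three fixtures are packaged:

* the curated CL/P candidate-gene catalog (systematic-review summary),
* the published per-miRNA enrichment table (significant miRNAs, their
  families and candidate-gene target lists, printed FDR values), and
* the published family rollup (genes targeted by >= 2 known families).

The enrichment table ships the *published* gene lists; re-deriving the
printed FDR values would require the raw prediction databases, so the
fixture's ``fdr`` column is carried through verbatim where a row object
needs a q-value.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import GeneCatalog, load_gene_catalog
from .enrichment import EnrichmentRow, FamilyMap
from .targets import TargetMap, build_target_map

__all__ = [
    "data_path",
    "catalog_manifest",
    "load_candidate_gene_catalog",
    "load_published_enrichment_frame",
    "load_published_target_map",
    "load_published_enrichment_rows",
    "load_published_family_rollup",
    "load_family_map",
]


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("cleftminer") / "data" / name)


def catalog_manifest() -> dict:
    return json.loads(data_path("clp_catalog_manifest.json").read_text())


def load_candidate_gene_catalog() -> GeneCatalog:
    """The curated candidate-gene catalog (one record per distinct symbol)."""
    return load_gene_catalog(data_path("clp_gene_catalog.tsv"), name="clp_candidates")


def load_published_enrichment_frame() -> pd.DataFrame:
    """Raw published enrichment table: family, mirna, fdr, genes (list)."""
    df = pd.read_csv(
        data_path("mirna_enrichment_table.tsv"), sep="\t", comment="#", dtype=str
    )
    df["fdr"] = df["fdr"].astype(float)
    df["genes"] = df["genes"].map(lambda s: [g for g in s.split(",") if g])
    return df


def load_family_map() -> FamilyMap:
    return FamilyMap.from_tsv(data_path("mirna_family_map.tsv"))


def load_published_target_map() -> TargetMap:
    """TargetMap over the published gene lists (universe = union of genes)."""
    df = load_published_enrichment_frame()
    pairs = {(row.mirna, g) for row in df.itertuples(index=False) for g in row.genes}
    return build_target_map(pairs, universe_mode="all_target_genes")


def load_published_enrichment_rows() -> list[EnrichmentRow]:
    """The published table as significant :class:`EnrichmentRow` objects.

    The printed gene list is the overlap set; the printed FDR stands in for
    both p and q (raw p-values were not published).  K and N are the size
    of the union of all listed genes, the only universe recoverable from
    the table itself.
    """
    df = load_published_enrichment_frame()
    fam = load_family_map()
    union = sorted({g for genes in df["genes"] for g in genes})
    N = K = len(union)
    rows = []
    for row in df.itertuples(index=False):
        overlap = frozenset(row.genes)
        rows.append(
            EnrichmentRow(
                mirna=row.mirna,
                family=fam.family(row.mirna),
                overlap_genes=overlap,
                k=len(overlap),
                K=K,
                n=len(overlap),
                N=N,
                p=row.fdr,
                q=row.fdr,
                significant=True,
            )
        )
    rows.sort(key=lambda r: (r.q, r.p, r.mirna))
    return rows


def load_published_family_rollup() -> pd.DataFrame:
    """Published gene-by-family-count rollup (genes with >= 2 known families)."""
    df = pd.read_csv(
        data_path("mirna_family_rollup.tsv"), sep="\t", comment="#", dtype=str
    )
    df["n_families"] = df["n_families"].astype(int)
    return df
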