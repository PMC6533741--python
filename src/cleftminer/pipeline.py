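"""End-to-end orchestration: configured runs that write the result tables.

The two pipelines mirror the study design: ``run_mirna_pipeline`` goes from
raw interaction evidence to the enrichment table and family rollup;
``run_tdt_pipeline`` goes from PED/MAP trios and gene intervals to a
per-SNP TDT table and a top-marker-per-gene summary.  Every run writes a
``metadata.json`` recording thresholds, sizes and the seed, sufficient to
replay the run; outputs are deterministically sorted so reruns are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .catalog import load_gene_catalog
from .enrichment import FamilyMap, MiRNAEnrichment
from .errors import CleftminerError
from .targets import build_target_map, consensus_pairs, filter_validated, load_interactions
from .tdt import SignificanceTiers, TrioTDT, assign_genes, read_bed, read_trios

logger = logging.getLogger("cleftminer.pipeline")

__all__ = ["RunConfig", "run_mirna_pipeline", "run_tdt_pipeline"]


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run.

    Thresholds default to the study's choices: miRNA FDR 0.1, pathway FDR
    0.05, TDT alpha 0.05, minimum pathway overlap 4, two-source prediction
    consensus, family rollup at >= 2 families, no gene flank.
    """

    # inputs
    catalog: str | None = None
    interactions: list[str] = field(default_factory=list)
    family_map: str | None = None
    gmt: str | None = None
    ped: str | None = None
    map: str | None = None
    genes_bed: str | None = None
    # thresholds
    fdr_threshold: float = 0.1
    pathway_fdr: float = 0.05
    alpha: float = 0.05
    min_overlap: int = 4
    min_sources: int = 2
    min_families: int = 2
    flank: int = 0
    universe: str | None = None  # optional explicit background gene list (one per line)
    # misc
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def _validate_thresholds(self) -> None:
        for name, v, lo, hi in (
            ("fdr_threshold", self.fdr_threshold, 0, 1),
            ("pathway_fdr", self.pathway_fdr, 0, 1),
            ("alpha", self.alpha, 0, 1),
        ):
            if not (lo < v <= hi):
                raise CleftminerError(f"{name} must lie in ({lo}, {hi}]")
        if self.min_sources < 1 or self.min_overlap < 0 or self.flank < 0:
            raise CleftminerError("min_sources >= 1, min_overlap >= 0, flank >= 0")


def _stage(name: str):
    """Context manager logging stage timings to stderr."""
    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: failed after %.2fs", name, dt)
            return False

    return _Stage()


def _wrap_stage_errors(stage: str, exc: Exception) -> CleftminerError:
    return CleftminerError(f"[{stage}] {exc}")


def run_mirna_pipeline(config: RunConfig) -> dict:
    """Interactions -> consensus -> validated filter -> enrichment -> rollup.

    Writes ``mirna_enrichment.tsv``, ``gene_family_counts.tsv`` and
    ``metadata.json`` under ``config.outdir`` and returns the metadata dict.
    """
    config._validate_thresholds()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("load_interactions"):
        try:
            interactions = load_interactions(config.interactions)
        except CleftminerError as exc:
            raise _wrap_stage_errors("load_interactions", exc) from exc

    with _stage("consensus_and_validation"):
        pairs = consensus_pairs(interactions, min_sources=config.min_sources)
        pairs = filter_validated(pairs, interactions)
        if not pairs:
            raise CleftminerError(
                "[consensus_and_validation] no pairs survive the "
                f"{config.min_sources}-source consensus + validated filter"
            )

    with _stage("build_target_map"):
        if config.universe:
            universe = [
                g for g in Path(config.universe).read_text().split() if g.strip()
            ]
            tmap = build_target_map(
                pairs, universe_mode="explicit", explicit_universe=universe
            )
        else:
            tmap = build_target_map(pairs)

    with _stage("enrichment"):
        if not config.catalog:
            raise CleftminerError("[enrichment] config.catalog is required")
        catalog = load_gene_catalog(config.catalog)
        fam = (
            FamilyMap.from_tsv(config.family_map) if config.family_map else FamilyMap()
        )
        try:
            results = MiRNAEnrichment(tmap, catalog.symbol_set(), fam).fit(
                fdr_threshold=config.fdr_threshold
            )
        except CleftminerError as exc:
            raise _wrap_stage_errors("enrichment", exc) from exc

    with _stage("write_outputs"):
        results.table.to_csv(outdir / "mirna_enrichment.tsv", sep="\t", index=False)
        results.family_table(config.min_families).to_csv(
            outdir / "gene_family_counts.tsv", sep="\t", index=False
        )
        metadata = {
            "pipeline": "mirna_enrichment",
            "version": __version__,
            "config": asdict(config),
            "universe_size": len(tmap.universe),
            "foreground_in_universe": len(results.model.foreground_in_universe),
            "mirnas_tested": len(results.rows),
            "significant": len(results.significant),
        }
        (outdir / "metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
    return metadata


def run_tdt_pipeline(config: RunConfig) -> dict:
    """PED/MAP + BED -> per-SNP TDT table + per-gene top-marker summary."""
    config._validate_thresholds()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("read_trios"):
        if not (config.ped and config.map):
            raise CleftminerError("[read_trios] ped and map paths are required")
        try:
            panel = read_trios(config.ped, config.map)
        except CleftminerError as exc:
            raise _wrap_stage_errors("read_trios", exc) from exc

    with _stage("assign_genes"):
        gene_map = {}
        if config.genes_bed:
            intervals = read_bed(config.genes_bed)
            gene_map = assign_genes(panel.snps, intervals, flank_bp=config.flank)

    with _stage("tdt_scan"):
        tiers = SignificanceTiers(alpha=config.alpha)
        results = TrioTDT(panel, gene_map, tiers).fit()

    with _stage("write_outputs"):
        results.snp_table.to_csv(outdir / "tdt_snps.tsv", sep="\t", index=False)
        results.gene_table.to_csv(outdir / "tdt_genes.tsv", sep="\t", index=False)
        metadata = {
            "pipeline": "tdt_scan",
            "version": __version__,
            "config": asdict(config),
            "n_trios": panel.n_trios,
            "n_snps": panel.n_snps,
            "informative_snps": len(results.snp_results),
            "genes_tested": results.n_genes,
            "candidate_wise_threshold": results.candidate_threshold,
            "mendelian_errors": results.n_mendel_errors,
        }
        (outdir / "metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
    return metadata
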