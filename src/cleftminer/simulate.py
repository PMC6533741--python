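"""Synthetic data generators with the statistical structure the analyses assume.

Two generators:

* :func:`simulate_target_universe` draws per-miRNA target sets from a gene
  universe.  "Null" miRNAs sample uniformly; "planted" miRNAs sample with
  foreground genes up-weighted by a relative odds ``enrichment_odds``, so
  their target sets are genuinely enriched and the enrichment model should
  recover them.

* :func:`simulate_trios` draws parent genotypes under Hardy-Weinberg
  equilibrium at a given minor-allele frequency and transmits alleles to
  the child: homozygous parents deterministically, heterozygous parents
  transmitting allele A with probability ``tau`` (0.5 = null; per-SNP
  overrides plant transmission distortion for power studies).

Simulated SNPs are independent loci: no linkage disequilibrium is modeled,
which is sufficient for testing the per-SNP statistics but not LD-aware
methods.  Both generators are deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError
from .targets import TargetMap, build_target_map
from .tdt import SNP, TrioPanel

__all__ = ["SyntheticSpec", "simulate_target_universe", "simulate_trios"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generators.

    Defaults mirror the structure of the real analyses: a universe of 3000
    background genes of which 150 are candidates, 50 miRNAs with target
    sets of 30-80 genes (3 of them enriched at odds 10), and 300 genotyped
    trios over 200 independent SNPs at minor-allele frequency 0.3 with fair
    (tau = 0.5) transmission unless a per-SNP distortion is planted.
    """

    seed: int = 0
    # target-universe generator
    n_genes_universe: int = 3000
    n_foreground: int = 150
    n_mirnas: int = 50
    target_size_range: tuple[int, int] = (30, 80)
    planted_mirnas: int = 3
    enrichment_odds: float = 10.0
    # trio generator
    n_trios: int = 300
    n_snps: int = 200
    maf: float = 0.3
    tau: float = 0.5
    distorted_snps: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_foreground > self.n_genes_universe:
            raise DomainError("n_foreground exceeds universe size")
        if self.planted_mirnas > self.n_mirnas:
            raise DomainError("planted_mirnas exceeds n_mirnas")
        lo, hi = self.target_size_range
        if not (1 <= lo <= hi):
            raise DomainError("target_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes_universe:
            raise DomainError("target size exceeds universe size")
        if self.enrichment_odds <= 0:
            raise DomainError("enrichment_odds must be positive")
        if not (0 < self.maf <= 0.5):
            raise DomainError("maf must lie in (0, 0.5]")
        if not (0 < self.tau < 1):
            raise DomainError("tau must lie in (0, 1)")
        for idx, t in self.distorted_snps:
            if not (0 <= idx < self.n_snps):
                raise DomainError(f"distorted SNP index {idx} out of range")
            if not (0 < t < 1):
                raise DomainError(f"distorted tau {t} out of (0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        d = dict(d)
        if "target_size_range" in d:
            d["target_size_range"] = tuple(d["target_size_range"])
        if "distorted_snps" in d:
            d["distorted_snps"] = [tuple(x) for x in d["distorted_snps"]]
        return cls(**d)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_target_universe(
    spec: SyntheticSpec,
) -> tuple[TargetMap, frozenset[str], dict[str, bool]]:
    """Draw a synthetic TargetMap, foreground set, and planted-truth labels.

    Returns ``(target_map, foreground, truth)`` where ``truth[mirna]`` is
    True for the planted (enriched) miRNAs.  The target-map universe is the
    full simulated gene universe, so N is ``spec.n_genes_universe``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = np.array(_gene_names(spec.n_genes_universe))
    foreground_mask = np.zeros(spec.n_genes_universe, dtype=bool)
    foreground_mask[: spec.n_foreground] = True
    foreground = frozenset(genes[foreground_mask])

    lo, hi = spec.target_size_range
    weights_planted = np.where(foreground_mask, spec.enrichment_odds, 1.0)
    weights_planted = weights_planted / weights_planted.sum()

    pairs: set[tuple[str, str]] = set()
    truth: dict[str, bool] = {}
    width = max(3, len(str(spec.n_mirnas)))
    for i in range(spec.n_mirnas):
        mirna = f"sim-miR-{i + 1:0{width}d}"
        planted = i < spec.planted_mirnas
        truth[mirna] = planted
        size = int(rng.integers(lo, hi + 1))
        if planted:
            targets = rng.choice(genes, size=size, replace=False, p=weights_planted)
        else:
            targets = rng.choice(genes, size=size, replace=False)
        pairs.update((mirna, g) for g in targets)

    tmap = build_target_map(
        pairs, universe_mode="explicit", explicit_universe=genes.tolist()
    )
    return tmap, foreground, truth


def simulate_trios(spec: SyntheticSpec) -> TrioPanel:
    """Draw a trio panel under HWE parents and tau-biased transmission.

    Allele A is the minor allele (frequency ``spec.maf``); heterozygous
    parents transmit A with probability ``tau`` (per-SNP overrides from
    ``spec.distorted_snps``).  Genotypes are complete (no missingness).
    """
    rng = np.random.default_rng(spec.seed)
    nt, ns = spec.n_trios, spec.n_snps
    tau = np.full(ns, spec.tau)
    for idx, t in spec.distorted_snps:
        tau[idx] = t

    # parental dosage of allele A under HWE
    father = rng.binomial(2, spec.maf, size=(nt, ns))
    mother = rng.binomial(2, spec.maf, size=(nt, ns))

    def transmit(parent: np.ndarray) -> np.ndarray:
        het_draw = (rng.random((nt, ns)) < tau).astype(np.int8)
        return np.where(parent == 2, 1, np.where(parent == 0, 0, het_draw))

    child = transmit(father) + transmit(mother)

    # panel stores dosage of allele B
    geno = np.stack([2 - father, 2 - mother, 2 - child], axis=1).astype(np.int8)
    width = max(4, len(str(ns)))
    snps = [
        SNP(f"snp{j + 1:0{width}d}", "1", 1000 * j + 500, "A", "B")
        for j in range(ns)
    ]
    return TrioPanel(snps, geno)
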