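"""Transmission disequilibrium test (TDT) over parent-offspring trios.

For each biallelic SNP, every heterozygous parent with a genotyped,
Mendelian-consistent child contributes one transmission: of allele A
(counted in ``b``) or allele B (counted in ``c``).  Under the null of no
association/linkage the transmitted allele is a fair coin, so

    chi2 = (b - c)^2 / (b + c)

is asymptotically chi-square with 1 df (McNemar's test).  Because only
within-family transmissions are compared, the statistic is robust to
population stratification.  Heterozygous x heterozygous matings with a
heterozygous child are phase-ambiguous and contribute one transmission of
each allele — the standard counting resolution.

Results are summarized per gene by the top (minimum-p) marker, with tiered
significance labels: genome-wide (5e-8), gene-wide (2.5e-6), and a
candidate-wise Bonferroni level alpha / #genes-tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2 as chi2_dist

from .errors import (
    DomainError,
    EmptyInputError,
    FormatError,
    LookupFailure,
    UninformativeSNP,
)
from .stats import bonferroni_threshold

logger = logging.getLogger("cleftminer.tdt")

__all__ = [
    "SNP",
    "TrioPanel",
    "TransmissionCounts",
    "TDTResult",
    "SignificanceTiers",
    "BedInterval",
    "read_bed",
    "read_trios",
    "count_transmissions",
    "transmission_counts",
    "tdt_statistic",
    "assign_genes",
    "TrioTDT",
    "TDTResults",
]

MISSING = -1  # genotype dosage sentinel


@dataclass(frozen=True)
class SNP:
    """One biallelic marker; ``pos`` is 1-based as in MAP files."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class TransmissionCounts:
    """Transmissions from heterozygous parents: ``b`` of allele A, ``c`` of B."""

    b: int
    c: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise DomainError("transmission counts must be non-negative")


@dataclass(frozen=True)
class TDTResult:
    snp_id: str
    b: int
    c: int
    chi2: float
    p: float
    genes: frozenset[str] = frozenset()
    tier: str = "ns"


@dataclass(frozen=True)
class SignificanceTiers:
    """Tiered significance thresholds for the per-gene scan summary."""

    genome_wide: float = 5e-8
    gene_wide: float = 2.5e-6
    alpha: float = 0.05

    def candidate_wise(self, n_genes: int) -> float:
        """Bonferroni level alpha / #genes actually tested."""
        return bonferroni_threshold(self.alpha, n_genes)

    def label(self, p: float, n_genes: int) -> str:
        if p < self.genome_wide:
            return "genome_wide"
        if p < self.gene_wide:
            return "gene_wide"
        if n_genes >= 1 and p < self.candidate_wise(n_genes):
            return "candidate_wise"
        return "ns"


class TrioPanel:
    """Genotypes of father/mother/child trios at a shared marker panel.

    Genotypes are stored as the dosage of ``allele_b`` (0, 1, 2) with ``-1``
    for missing, in an int8 array of shape ``(n_trios, 3, n_snps)`` with
    member order father, mother, child.
    """

    def __init__(
        self,
        snps: Sequence[SNP],
        genotypes: np.ndarray,
        trio_ids: Sequence[tuple[str, str]] | None = None,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 3 or genotypes.shape[1] != 3:
            raise FormatError("genotypes must have shape (n_trios, 3, n_snps)")
        if genotypes.shape[2] != len(snps):
            raise FormatError("genotype SNP dimension does not match SNP list")
        self.snps = list(snps)
        self.genotypes = genotypes
        self.trio_ids = list(trio_ids or [
            (f"fam{i + 1}", f"fam{i + 1}_C") for i in range(genotypes.shape[0])
        ])
        if len(self.trio_ids) != genotypes.shape[0]:
            raise FormatError("trio_ids length does not match genotype array")
        self._snp_index = {s.snp_id: i for i, s in enumerate(self.snps)}

    @property
    def n_trios(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise LookupFailure(f"unknown SNP id {snp_id!r}") from None

    # -- serialization ------------------------------------------------------

    def write_ped_map(self, ped_path: str | Path, map_path: str | Path) -> None:
        """Write PLINK-style text PED/MAP (alleles as stored; missing '0')."""
        with open(map_path, "w") as fh:
            for s in self.snps:
                fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")

        def allele_pair(snp: SNP, dosage: int) -> str:
            if dosage < 0:
                return "0 0"
            a, b = snp.allele_a, snp.allele_b
            return {0: f"{a} {a}", 1: f"{a} {b}", 2: f"{b} {b}"}[dosage]

        with open(ped_path, "w") as fh:
            for t, (fam, child_id) in enumerate(self.trio_ids):
                father_id = f"{child_id}_F"
                mother_id = f"{child_id}_M"
                members = [
                    (father_id, "0", "0", "1"),
                    (mother_id, "0", "0", "2"),
                    (child_id, father_id, mother_id, "1"),
                ]
                for m, (iid, fa, mo, sex) in enumerate(members):
                    geno = " ".join(
                        allele_pair(s, int(self.genotypes[t, m, j]))
                        for j, s in enumerate(self.snps)
                    )
                    fh.write(f"{fam} {iid} {fa} {mo} {sex} 2 {geno}\n")


def read_trios(ped_path: str | Path, map_path: str | Path) -> TrioPanel:
    """Assemble a :class:`TrioPanel` from PLINK-style text PED + MAP.

    Children are rows whose father and mother ids both resolve within the
    same family in the file; all other individuals only serve as parents.
    Multiallelic markers are rejected with a warning; missing genotypes use
    the '0' code.  Allele A is the lexicographically smaller observed allele
    (the TDT statistic is invariant to this labeling).
    """
    map_rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 4:
            chrom, snp_id, _, pos = parts
        elif len(parts) == 3:
            chrom, snp_id, pos = parts
        else:
            raise FormatError(f"{map_path}:{lineno}: expected 3 or 4 columns")
        try:
            map_rows.append((chrom, snp_id, int(pos)))
        except ValueError:
            raise FormatError(f"{map_path}:{lineno}: non-integer position {pos!r}")
    n_snps = len(map_rows)
    if n_snps == 0:
        raise EmptyInputError(f"{map_path}: no markers")

    individuals: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise FormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                f"({n_snps} markers), got {len(parts)}"
            )
        fam, iid, father, mother = parts[:4]
        alleles = parts[6:]
        key = (fam, iid)
        individuals[key] = {
            "father": father,
            "mother": mother,
            "alleles": [(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_snps)],
        }
        order.append(key)

    # per-SNP observed alleles -> biallelic coding
    snps: list[SNP] = []
    keep: list[int] = []
    codes: list[dict[str, int]] = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        observed = sorted(
            {
                a
                for ind in individuals.values()
                for a in ind["alleles"][j]
                if a != "0"
            }
        )
        if len(observed) > 2:
            warnings.warn(
                f"SNP {snp_id!r} has {len(observed)} alleles; multiallelic "
                "markers are excluded",
                stacklevel=2,
            )
            continue
        if len(observed) == 0:
            observed = ["A", "B"]
        elif len(observed) == 1:
            observed = [observed[0], "."]
        snps.append(SNP(snp_id, chrom, pos, observed[0], observed[1]))
        keep.append(j)
        codes.append({observed[0]: 0, observed[1]: 1})

    trios: list[tuple[str, str]] = []
    trio_members: list[tuple[tuple[str, str], ...]] = []
    for fam, iid in order:
        ind = individuals[(fam, iid)]
        father, mother = ind["father"], ind["mother"]
        if father == "0" and mother == "0":
            continue
        fkey, mkey = (fam, father), (fam, mother)
        if fkey not in individuals or mkey not in individuals:
            logger.info(
                "child %s/%s references absent parent(s); excluded", fam, iid
            )
            continue
        trios.append((fam, iid))
        trio_members.append((fkey, mkey, (fam, iid)))
    if not trios:
        warnings.warn("no complete trios found in pedigree", stacklevel=2)

    geno = np.full((len(trios), 3, len(snps)), MISSING, dtype=np.int8)
    for t, members in enumerate(trio_members):
        for m, key in enumerate(members):
            alleles = individuals[key]["alleles"]
            for sj, j in enumerate(keep):
                a1, a2 = alleles[j]
                if a1 == "0" or a2 == "0":
                    continue
                geno[t, m, sj] = codes[sj][a1] + codes[sj][a2]
    return TrioPanel(snps, geno, trios)


# ---------------------------------------------------------------------------
# transmission counting
# ---------------------------------------------------------------------------

def _count_all(panel: TrioPanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP transmission counts.

    Returns arrays ``(b, c, n_mendel_errors)`` over SNPs, where ``b`` counts
    allele-A and ``c`` allele-B transmissions from heterozygous parents.
    """
    F = panel.genotypes[:, 0, :].astype(np.int16)
    M = panel.genotypes[:, 1, :].astype(np.int16)
    C = panel.genotypes[:, 2, :].astype(np.int16)
    present = (F >= 0) & (M >= 0) & (C >= 0)
    # child's allele-B dosage must lie between the forced minimum and maximum
    c_min = (F == 2).astype(np.int16) + (M == 2).astype(np.int16)
    c_max = (F >= 1).astype(np.int16) + (M >= 1).astype(np.int16)
    consistent = (C >= c_min) & (C <= c_max)
    mendel_err = present & ~consistent
    ok = present & consistent

    b_trans = np.zeros(F.shape, dtype=np.int16)  # allele A
    c_trans = np.zeros(F.shape, dtype=np.int16)  # allele B

    f_het = ok & (F == 1) & (M != 1)
    tB = np.where(f_het, C - M // 2, 0)
    c_trans += np.where(f_het, tB, 0)
    b_trans += np.where(f_het, 1 - tB, 0)

    m_het = ok & (M == 1) & (F != 1)
    tB = np.where(m_het, C - F // 2, 0)
    c_trans += np.where(m_het, tB, 0)
    b_trans += np.where(m_het, 1 - tB, 0)

    # het x het: child dosage equals the number of B transmissions; a
    # heterozygous child is phase-ambiguous -> one transmission of each.
    both = ok & (F == 1) & (M == 1)
    c_trans += np.where(both, C, 0)
    b_trans += np.where(both, 2 - C, 0)

    return (
        b_trans.sum(axis=0).astype(np.int64),
        c_trans.sum(axis=0).astype(np.int64),
        mendel_err.sum(axis=0).astype(np.int64),
    )


def transmission_counts(panel: TrioPanel) -> pd.DataFrame:
    """Per-SNP ``b``/``c`` counts and Mendelian-error trio counts."""
    b, c, err = _count_all(panel)
    return pd.DataFrame(
        {
            "snp": [s.snp_id for s in panel.snps],
            "b": b,
            "c": c,
            "mendel_errors": err,
        }
    )


def count_transmissions(panel: TrioPanel, snp_id: str) -> TransmissionCounts:
    """Transmission counts at one SNP (Mendelian-error trios excluded)."""
    j = panel.snp_index(snp_id)
    b, c, err = _count_all(panel)
    if err[j]:
        logger.info("SNP %s: %d Mendelian-error trio(s) excluded", snp_id, err[j])
    return TransmissionCounts(int(b[j]), int(c[j]))


def tdt_statistic(counts: TransmissionCounts) -> tuple[float, float]:
    """McNemar chi-square ``(b-c)^2/(b+c)`` and its upper-tail chi2(1) p."""
    total = counts.b + counts.c
    if total == 0:
        raise UninformativeSNP("no informative transmissions (b + c == 0)")
    chi2 = (counts.b - counts.c) ** 2 / total
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedInterval:
    """BED record: 0-based half-open [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str


def read_bed(path: str | Path) -> list[BedInterval]:
    """Read BED3+name gene intervals."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: BED needs chrom/start/end/name")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        if start < 0 or end < start:
            raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
        out.append(BedInterval(parts[0], start, end, parts[3]))
    return out


def assign_genes(
    snps: Sequence[SNP],
    intervals: Sequence[BedInterval],
    flank_bp: int = 0,
) -> dict[str, frozenset[str]]:
    """Map each SNP to the genes whose (flank-extended) interval contains it.

    BED intervals are 0-based half-open; MAP positions are 1-based, so a SNP
    at position ``p`` is tested as point ``p - 1``.  With ``flank_bp`` the
    window becomes ``[start - flank, end + flank)``.
    """
    if flank_bp < 0:
        raise DomainError("flank_bp must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        lo = max(0, iv.start - flank_bp)
        hi = iv.end + flank_bp
        if hi <= lo:
            continue
        trees.setdefault(iv.chrom, IntervalTree()).addi(lo, hi, iv.name)
    out = {}
    for s in snps:
        tree = trees.get(s.chrom)
        hits = tree[s.pos - 1] if tree is not None else ()
        out[s.snp_id] = frozenset(h.data for h in hits)
    return out


# ---------------------------------------------------------------------------
# scan model
# ---------------------------------------------------------------------------

class TrioTDT:
    """TDT association scan over a trio panel, summarized per gene.

    Parameters
    ----------
    panel : TrioPanel
        Genotyped trios.
    gene_map : mapping, optional
        ``snp_id -> iterable of gene symbols``; build one with
        :func:`assign_genes`.  SNPs absent from the map (or mapped to an
        empty set) appear in the per-SNP output but not in the gene summary.
    tiers : SignificanceTiers
        Thresholds used to label each gene's top marker.
    """

    def __init__(
        self,
        panel: TrioPanel,
        gene_map: Mapping[str, Iterable[str]] | None = None,
        tiers: SignificanceTiers = SignificanceTiers(),
    ) -> None:
        if panel.n_trios == 0 or panel.n_snps == 0:
            raise EmptyInputError("panel has no trios or no SNPs")
        self.panel = panel
        self.gene_map = {
            k: frozenset(v) for k, v in (gene_map or {}).items()
        }
        self.tiers = tiers

    def fit(self) -> "TDTResults":
        b, c, err = _count_all(self.panel)
        total = b + c
        informative = total > 0
        if not informative.any():
            warnings.warn("no informative SNPs in panel", stacklevel=2)
        chi2 = np.zeros_like(b, dtype=float)
        p = np.ones_like(b, dtype=float)
        chi2[informative] = (b[informative] - c[informative]) ** 2 / total[informative]
        p[informative] = chi2_dist.sf(chi2[informative], df=1)

        # genes tested = genes with >= 1 informative SNP
        genes_tested = sorted(
            {
                g
                for j, s in enumerate(self.panel.snps)
                if informative[j]
                for g in self.gene_map.get(s.snp_id, ())
            }
        )
        n_genes = len(genes_tested)
        results = []
        for j, s in enumerate(self.panel.snps):
            if not informative[j]:
                continue
            results.append(
                TDTResult(
                    snp_id=s.snp_id,
                    b=int(b[j]),
                    c=int(c[j]),
                    chi2=float(chi2[j]),
                    p=float(p[j]),
                    genes=self.gene_map.get(s.snp_id, frozenset()),
                    tier=self.tiers.label(float(p[j]), n_genes),
                )
            )
        results.sort(key=lambda r: (r.p, r.snp_id))
        return TDTResults(self, results, genes_tested, int(err.sum()))


class TDTResults:
    """Fitted TDT scan: per-SNP results and a top-marker-per-gene summary."""

    def __init__(
        self,
        model: TrioTDT,
        snp_results: list[TDTResult],
        genes_tested: list[str],
        n_mendel_errors: int,
    ) -> None:
        self.model = model
        self.snp_results = snp_results
        self.genes_tested = genes_tested
        self.n_mendel_errors = n_mendel_errors

    @property
    def n_genes(self) -> int:
        return len(self.genes_tested)

    @property
    def candidate_threshold(self) -> float | None:
        if self.n_genes == 0:
            return None
        return self.model.tiers.candidate_wise(self.n_genes)

    @property
    def snp_table(self) -> pd.DataFrame:
        snp_meta = {s.snp_id: s for s in self.model.panel.snps}
        return pd.DataFrame(
            [
                {
                    "snp": r.snp_id,
                    "chrom": snp_meta[r.snp_id].chrom,
                    "pos": snp_meta[r.snp_id].pos,
                    "genes": ",".join(sorted(r.genes)),
                    "b": r.b,
                    "c": r.c,
                    "chi2": r.chi2,
                    "p": r.p,
                    "tier": r.tier,
                }
                for r in self.snp_results
            ],
            columns=["snp", "chrom", "pos", "genes", "b", "c", "chi2", "p", "tier"],
        )

    @property
    def gene_table(self) -> pd.DataFrame:
        """One row per tested gene: its top (minimum-p) marker.

        Gene-level p is the top marker's p without intra-gene correction;
        neighboring SNPs in a gene are typically in strong LD, so a
        per-gene Bonferroni would overcorrect.
        """
        best: dict[str, TDTResult] = {}
        for r in self.snp_results:
            for g in r.genes:
                cur = best.get(g)
                if cur is None or (r.p, r.snp_id) < (cur.p, cur.snp_id):
                    best[g] = r
        rows = [
            {
                "top_marker": r.snp_id,
                "gene": g,
                "b": r.b,
                "c": r.c,
                "chi2": r.chi2,
                "p": r.p,
                "tier": r.tier,
            }
            for g, r in best.items()
        ]
        df = pd.DataFrame(
            rows, columns=["top_marker", "gene", "b", "c", "chi2", "p", "tier"]
        )
        return df.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "trio TDT scan",
            "=" * 46,
            f"trios                {self.model.panel.n_trios}",
            f"informative SNPs     {len(self.snp_results)}",
            f"genes tested         {self.n_genes}",
            f"Mendelian errors     {self.n_mendel_errors} (trio x SNP, excluded)",
        ]
        if self.candidate_threshold is not None:
            lines.append(
                f"candidate-wise p     {self.candidate_threshold:.3g} "
                f"(alpha={self.model.tiers.alpha}/{self.n_genes})"
            )
        gt = self.gene_table
        hits = gt[gt["tier"] != "ns"]
        if not hits.empty:
            lines.append("-" * 46)
            lines.append(f"{'gene':<12}{'top marker':<14}{'p':>12}  tier")
            for row in hits.itertuples(index=False):
                lines.append(
                    f"{row.gene:<12}{row.top_marker:<14}{row.p:>12.3g}  {row.tier}"
                )
        return "\n".join(lines)
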