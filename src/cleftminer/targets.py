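"""Integration of miRNA-target interaction evidence into a TargetMap.

The analysis combines several computational target-prediction sources
(miRanda/PITA/TargetScan-style exports) with an experimentally-validated
interaction source (miRTarbase-style).  A miRNA-gene pair survives when it
is predicted by at least ``min_sources`` distinct prediction sources *and*
carries validated evidence.  The surviving pairs form a :class:`TargetMap`:
per-miRNA target gene sets over a declared background universe.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import normalize_symbol
from .errors import EmptyInputError, FormatError

__all__ = [
    "Interaction",
    "TargetMap",
    "load_interactions",
    "consensus_pairs",
    "filter_validated",
    "build_target_map",
]

_TRUE = {"true", "t", "1", "yes", "y"}


def _canon_mirna(raw: str) -> str:
    """Canonical matching key for a miRNA id (case-insensitive, trimmed)."""
    return str(raw).strip().lower()


@dataclass(frozen=True)
class Interaction:
    """One unit of miRNA-target evidence from one source database."""

    source: str
    mirna: str
    gene: str
    validated: bool = False

    def __post_init__(self) -> None:
        if not self.source.strip():
            raise FormatError("interaction with empty source")
        if not self.mirna.strip():
            raise FormatError("interaction with empty miRNA id")
        if not self.gene:
            raise FormatError("interaction with empty gene symbol")


def load_interactions(paths: Sequence[str | Path]) -> list[Interaction]:
    """Read and concatenate interaction TSVs.

    Each file needs columns ``source``, ``mirna``, ``gene``; ``validated``
    is optional and defaults to false.  Gene symbols are normalized; exact
    duplicates (same source/mirna/gene, case-insensitive miRNA match) are
    collapsed, keeping the validated flag if any copy carries it.
    """
    if not paths:
        raise EmptyInputError("no interaction files given")
    frames = []
    for p in paths:
        p = Path(p)
        try:
            df = pd.read_csv(p, sep="\t", comment="#", dtype=str).fillna("")
        except (OSError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"{p}: unreadable interaction file ({exc})") from exc
        missing = [c for c in ("source", "mirna", "gene") if c not in df.columns]
        if missing:
            raise FormatError(f"{p}: missing required column(s) {missing}")
        if "validated" not in df.columns:
            df["validated"] = "false"
        frames.append(df[["source", "mirna", "gene", "validated"]])
    merged = pd.concat(frames, ignore_index=True)

    # collapse duplicates, OR-ing the validated flag; keep first spelling
    seen: dict[tuple[str, str, str], int] = {}
    out: list[Interaction] = []
    for row in merged.itertuples(index=False):
        source = row.source.strip()
        mirna = row.mirna.strip()
        gene = normalize_symbol(row.gene)
        validated = row.validated.strip().lower() in _TRUE
        key = (source, _canon_mirna(mirna), gene)
        if key in seen:
            i = seen[key]
            if validated and not out[i].validated:
                out[i] = Interaction(out[i].source, out[i].mirna, out[i].gene, True)
            continue
        seen[key] = len(out)
        out.append(Interaction(source, mirna, gene, validated))
    return out


def consensus_pairs(
    interactions: Iterable[Interaction], min_sources: int = 2
) -> set[tuple[str, str]]:
    """Pairs supported by at least ``min_sources`` distinct prediction sources.

    Only predicted (``validated == False``) rows count as prediction support;
    a validated-evidence source therefore never inflates the consensus count.
    Returns ``(mirna, gene)`` pairs with the miRNA's first-seen spelling.
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    support: dict[tuple[str, str], set[str]] = defaultdict(set)
    spelling: dict[tuple[str, str], tuple[str, str]] = {}
    for it in interactions:
        key = (_canon_mirna(it.mirna), it.gene)
        spelling.setdefault(key, (it.mirna, it.gene))
        if not it.validated:
            support[key].add(it.source)
    return {
        spelling[key] for key, sources in support.items() if len(sources) >= min_sources
    }


def filter_validated(
    pairs: set[tuple[str, str]], interactions: Iterable[Interaction]
) -> set[tuple[str, str]]:
    """Retain pairs that carry validated evidence in any source (subset of input)."""
    validated = {
        (_canon_mirna(it.mirna), it.gene) for it in interactions if it.validated
    }
    return {p for p in pairs if (_canon_mirna(p[0]), p[1]) in validated}


@dataclass
class TargetMap:
    """Per-miRNA target gene sets over a declared background universe.

    Attributes
    ----------
    targets : dict
        miRNA id -> frozenset of target gene symbols (all within universe).
    universe : frozenset
        Background gene set N for enrichment.
    provenance : dict
        Optional ``(mirna, gene) -> frozenset of supporting source names``.
    """

    targets: dict[str, frozenset[str]]
    universe: frozenset[str]
    provenance: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise EmptyInputError("TargetMap with empty universe")
        for m, genes in self.targets.items():
            if not genes:
                raise FormatError(f"miRNA {m!r} has no targets")
            stray = genes - self.universe
            if stray:
                raise FormatError(
                    f"targets of {m!r} outside universe: {sorted(stray)[:5]}"
                )

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.mirnas:
            for g in sorted(self.targets[m]):
                srcs = self.provenance.get((m, g), frozenset())
                rows.append(
                    {
                        "mirna": m,
                        "gene": g,
                        "n_sources": len(srcs),
                        "validated": True,
                    }
                )
        return pd.DataFrame(rows, columns=["mirna", "gene", "n_sources", "validated"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, universe: Iterable[str] | None = None) -> "TargetMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        if not {"mirna", "gene"} <= set(df.columns):
            raise FormatError(f"{path}: need columns mirna, gene")
        pairs = {(m.strip(), normalize_symbol(g)) for m, g in zip(df["mirna"], df["gene"])}
        mode = "explicit" if universe is not None else "all_target_genes"
        return build_target_map(pairs, universe_mode=mode, explicit_universe=universe)


def build_target_map(
    pairs: set[tuple[str, str]],
    universe_mode: str = "all_target_genes",
    explicit_universe: Iterable[str] | None = None,
    provenance: Mapping[tuple[str, str], Iterable[str]] | None = None,
) -> TargetMap:
    """Assemble a :class:`TargetMap` from surviving ``(mirna, gene)`` pairs.

    ``universe_mode="all_target_genes"`` (default) takes the union of all
    target genes as background; ``"explicit"`` requires
    ``explicit_universe`` to cover every target gene.
    """
    if not pairs:
        raise EmptyInputError("no miRNA-gene pairs to build a target map from")
    targets: dict[str, set[str]] = defaultdict(set)
    for mirna, gene in pairs:
        targets[mirna].add(gene)
    all_genes = frozenset(g for gs in targets.values() for g in gs)
    if universe_mode == "all_target_genes":
        universe = all_genes
    elif universe_mode == "explicit":
        if explicit_universe is None:
            raise ValueError("explicit universe_mode needs explicit_universe")
        universe = frozenset(normalize_symbol(g) for g in explicit_universe)
        stray = all_genes - universe
        if stray:
            raise ValueError(
                f"explicit universe misses target gene(s): {sorted(stray)[:5]}"
            )
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    prov = {}
    if provenance:
        prov = {k: frozenset(v) for k, v in provenance.items() if k in pairs}
    return TargetMap(
        targets={m: frozenset(gs) for m, gs in targets.items()},
        universe=universe,
        provenance=prov,
    )
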