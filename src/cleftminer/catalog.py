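"""Candidate-gene catalog: the curated foreground set for enrichment analyses.

The catalog is a small, ordered table of HGNC-style gene symbols with their
cytogenetic locus and a syndromic/nonsyndromic classification.  It defines
the foreground ("interesting") gene set that every downstream enrichment
test compares against a background universe.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import EmptyInputError, FormatError

__all__ = [
    "GeneRecord",
    "GeneCatalog",
    "normalize_symbol",
    "load_gene_catalog",
]

_WS = re.compile(r"\s+")

#: Allowed values of :attr:`GeneRecord.syndromic_status`.
SYNDROMIC_STATUSES = ("nonsyndromic", "syndromic", "both")


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol: trim, uppercase, drop internal whitespace.

    Total function: any string (including empty) maps to a string.

    >>> normalize_symbol(" irf6 ")
    'IRF6'
    """
    return _WS.sub("", str(raw).strip()).upper()


@dataclass
class GeneRecord:
    """One curated candidate gene.

    Parameters
    ----------
    symbol : str
        HGNC-style symbol, normalized to an uppercase token.
    aliases : list of str
        Alternate symbols; never allowed to collide with another record's
        primary symbol.
    locus : str
        Cytoband string such as ``"1q32.2"``, or empty when unknown.
    syndromic_status : str
        One of ``nonsyndromic``, ``syndromic``, ``both``.
    syndrome_names : list of str
        Named syndromes for syndromic entries (e.g. ``"Van der Woude
        syndrome"``).
    name : str
        Free-text gene name (descriptive only).
    """

    symbol: str
    aliases: list[str] = field(default_factory=list)
    locus: str = ""
    syndromic_status: str = "nonsyndromic"
    syndrome_names: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.symbol = normalize_symbol(self.symbol)
        if not self.symbol:
            raise FormatError("gene record with empty symbol")
        if self.syndromic_status not in SYNDROMIC_STATUSES:
            raise FormatError(
                f"{self.symbol}: syndromic_status {self.syndromic_status!r} "
                f"not one of {SYNDROMIC_STATUSES}"
            )
        self.aliases = [normalize_symbol(a) for a in self.aliases if normalize_symbol(a)]


class GeneCatalog:
    """Ordered, duplicate-free collection of :class:`GeneRecord`.

    Symbols are unique after normalization; aliases that collide with a
    primary symbol of another record are dropped with a warning.
    """

    def __init__(self, records: Iterable[GeneRecord], name: str = "catalog") -> None:
        self.name = name
        self._records: list[GeneRecord] = []
        self._index: dict[str, GeneRecord] = {}
        for rec in records:
            self._add(rec)
        if not self._records:
            raise EmptyInputError(f"catalog {name!r} has no records")
        self._drop_colliding_aliases()

    def _add(self, rec: GeneRecord) -> None:
        if rec.symbol in self._index:
            warnings.warn(
                f"duplicate gene symbol {rec.symbol!r} collapsed in catalog",
                stacklevel=3,
            )
            return
        self._index[rec.symbol] = rec
        self._records.append(rec)

    def _drop_colliding_aliases(self) -> None:
        for rec in self._records:
            kept = []
            for alias in rec.aliases:
                if alias in self._index and alias != rec.symbol:
                    warnings.warn(
                        f"alias {alias!r} of {rec.symbol!r} collides with a "
                        "primary symbol and was dropped",
                        stacklevel=3,
                    )
                else:
                    kept.append(alias)
            rec.aliases = kept

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self._index

    def __getitem__(self, symbol: str) -> GeneRecord:
        return self._index[normalize_symbol(symbol)]

    @property
    def symbols(self) -> list[str]:
        """Normalized symbols in catalog order."""
        return [r.symbol for r in self._records]

    def symbol_set(self) -> frozenset[str]:
        """The catalog as a foreground gene set."""
        return frozenset(self._index)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "symbol": r.symbol,
                "name": r.name,
                "locus": r.locus,
                "syndromic_status": r.syndromic_status,
                "syndromes": ";".join(r.syndrome_names),
                "aliases": ",".join(r.aliases),
            }
            for r in self._records
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneCatalog({self.name!r}, n={len(self)})"


_REQUIRED_COLUMNS = ("symbol", "locus", "syndromic_status")


def load_gene_catalog(path: str | Path, name: str | None = None) -> GeneCatalog:
    """Read a catalog from a UTF-8 TSV with a header row.

    Required columns: ``symbol``, ``locus``, ``syndromic_status``.  Optional:
    ``name``, ``syndromes`` (``;``-separated), ``aliases`` (``,``-separated).
    Lines starting with ``#`` are comments.  Duplicate symbols (after
    normalization) are collapsed with a warning; row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: catalog file is empty") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: catalog has a header but no rows")
    records = []
    for _, row in df.iterrows():
        records.append(
            GeneRecord(
                symbol=row["symbol"],
                locus=row["locus"].strip(),
                syndromic_status=row["syndromic_status"].strip() or "nonsyndromic",
                syndrome_names=[
                    s.strip() for s in row.get("syndromes", "").split(";") if s.strip()
                ],
                aliases=[
                    a.strip() for a in row.get("aliases", "").split(",") if a.strip()
                ],
                name=row.get("name", "").strip(),
            )
        )
    return GeneCatalog(records, name=name or path.stem)
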