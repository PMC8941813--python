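"""Surface-protein catalog: identifier canonicalization and set filtering.

The catalog is a local two-column TSV (``accession<TAB>gene_symbol``).
Membership is decided by gene symbol (case-insensitive) or accession
(case-sensitive after trimming); a hit on either counts as surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from surfscore.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ("accession", "gene_symbol")


def canonicalize(identifier: str) -> str:
    """Canonical form of a gene/protein identifier: trimmed, uppercased.

    Idempotent: ``canonicalize(canonicalize(x)) == canonicalize(x)``.

    Raises
    ------
    ValidationError
        If the identifier is empty (or whitespace only).
    """
    if not isinstance(identifier, str) or not identifier.strip():
        raise ValidationError("identifier: empty identifier cannot be canonicalized")
    return identifier.strip().upper()


@dataclass
class SurfaceomeCatalog:
    """Set of (accession, gene_symbol) surface-protein entries with indexes."""

    entries: list[tuple[str, str]]
    _symbols: set[str] = field(init=False, repr=False)
    _accessions: set[str] = field(init=False, repr=False)
    symbol_to_accession: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen_acc: dict[str, str] = {}
        cleaned: list[tuple[str, str]] = []
        for accession, symbol in self.entries:
            accession = accession.strip()
            if not accession or not symbol or not symbol.strip():
                raise ValidationError("entries: accession and gene_symbol must be non-empty")
            symbol = canonicalize(symbol)
            if accession in seen_acc:
                logger.warning("duplicate accession %s collapsed", accession)
                continue
            seen_acc[accession] = symbol
            cleaned.append((accession, symbol))
        self.entries = cleaned
        self._symbols = {s for _, s in cleaned}
        self._accessions = set(seen_acc)
        self.symbol_to_accession = {s: a for a, s in cleaned}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, identifier: str) -> bool:
        """Surface membership by symbol (case-insensitive) or accession."""
        return (
            canonicalize(identifier) in self._symbols
            or identifier.strip() in self._accessions
        )

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self._symbols)

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(self._accessions)


def read_catalog(path: str | Path) -> SurfaceomeCatalog:
    """Parse a catalog TSV with header ``accession<TAB>gene_symbol``.

    Duplicate accessions are collapsed (first occurrence wins) with a
    logged warning. Raises :class:`FormatError` on a missing/invalid
    header or an empty file.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty catalog file")
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if header != CATALOG_COLUMNS:
        raise FormatError(
            f"{path}: expected header {CATALOG_COLUMNS!r}, found {header!r}"
        )
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, found {len(parts)}")
        entries.append((parts[0], parts[1]))
    if not entries:
        raise FormatError(f"{path}: catalog has a header but no entries")
    catalog = SurfaceomeCatalog(entries)
    logger.info("read %d catalog rows -> %d entries from %s", len(entries), len(catalog), path)
    return catalog


def filter_surface(genes: set[str], catalog: SurfaceomeCatalog) -> set[str]:
    """Restrict a gene/protein identifier set to catalog-annotated entries.

    Returns the canonicalized identifiers that match the catalog by
    symbol or accession; always a subset of the canonicalized input.
    """
    return {canonicalize(g) for g in genes if g.strip() and g in catalog}


def write_gene_set(genes: set[str], path: str | Path) -> None:
    """Export an identifier set as a one-column TSV (sorted)."""
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))
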