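"""Catalog of Drosophila innate-immunity genes grouped by functional class.

The catalog drives every class-level statistic in the package: antimicrobial
peptides (AMPs), lysozymes, lectins, the pattern-recognition receptor families
(PGRP, GNBP), and the three canonical signaling pathways (Toll, IMD, JAK-STAT).
The packaged default ships the 14 canonical head-expressed AMPs plus the
immune genes most often screened alongside them; all non-AMP panels are
user-extensible via TSV catalogs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

IMMUNE_CLASSES = frozenset(
    {
        "AMP",
        "lysozyme",
        "lectin",
        "PGRP",
        "GNBP",
        "Toll_pathway",
        "IMD_pathway",
        "JAKSTAT_pathway",
        "other",
    }
)

#: The 14 canonical antimicrobial peptide genes in the default catalog.
DEFAULT_AMP_PANEL = (
    "AttA", "AttB", "AttC", "AttD",
    "CecA1", "CecA2", "CecB", "CecC",
    "DptA", "DptB",
    "Drs", "Def", "Dro", "Mtk",
)


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog input."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene symbol with its immune class and alternative symbols."""

    symbol: str
    immune_class: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogError("gene symbol must be non-empty")
        if self.immune_class not in IMMUNE_CLASSES:
            raise CatalogError(
                f"unknown immune_class {self.immune_class!r} for gene "
                f"{self.symbol!r}; expected one of {sorted(IMMUNE_CLASSES)}"
            )


class GeneCatalog:
    """Alias-aware, case-insensitive collection of :class:`GeneRecord`."""

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: tuple[GeneRecord, ...] = tuple(records)
        self._lookup: dict[str, GeneRecord] = {}
        for rec in self.records:
            for name in (rec.symbol, *rec.aliases):
                key = name.casefold()
                prior = self._lookup.get(key)
                if prior is not None and prior.symbol != rec.symbol:
                    raise CatalogError(
                        f"duplicate symbol/alias {name!r} maps to both "
                        f"{prior.symbol!r} and {rec.symbol!r}"
                    )
                self._lookup[key] = rec
        symbols = [r.symbol.casefold() for r in self.records]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise CatalogError(f"duplicate gene symbol(s): {dupes}")

    @property
    def class_index(self) -> dict[str, tuple[str, ...]]:
        """Mapping immune_class -> member symbols, in record order."""
        index: dict[str, list[str]] = {}
        for rec in self.records:
            index.setdefault(rec.immune_class, []).append(rec.symbol)
        return {k: tuple(v) for k, v in index.items()}

    def members(self, immune_class: str) -> tuple[str, ...]:
        return self.class_index.get(immune_class, ())

    def classify(self, symbol: str) -> Optional[str]:
        """Return the immune class of *symbol* (alias- and case-insensitive),
        or None if the symbol is not in the catalog."""
        rec = self._lookup.get(symbol.casefold())
        return rec.immune_class if rec else None

    def canonical_symbol(self, symbol: str) -> Optional[str]:
        rec = self._lookup.get(symbol.casefold())
        return rec.symbol if rec else None

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self._lookup

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneCatalog):
            return NotImplemented
        return self.records == other.records

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["symbol", "immune_class", "aliases"])
            for rec in self.records:
                writer.writerow([rec.symbol, rec.immune_class, ";".join(rec.aliases)])


def classify(catalog: GeneCatalog, symbol: str) -> Optional[str]:
    """Functional form of :meth:`GeneCatalog.classify`."""
    return catalog.classify(symbol)


def load_catalog(path: str | Path = "default") -> GeneCatalog:
    """Load a gene catalog from a TSV file, or the packaged default.

    The file must have a header ``symbol\\timmune_class\\taliases``; the
    aliases column is optional and semicolon-separated.
    """
    if str(path) == "default":
        source = resources.files("immunoccur.data") / "default_catalog.tsv"
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise CatalogError("empty catalog file")
    reader = csv.DictReader(lines, delimiter="\t")
    fields = reader.fieldnames or []
    missing = {"symbol", "immune_class"} - set(fields)
    if missing:
        raise CatalogError(f"catalog file missing column(s): {sorted(missing)}")
    records = []
    for row in reader:
        aliases = tuple(
            a.strip() for a in (row.get("aliases") or "").split(";") if a.strip()
        )
        records.append(
            GeneRecord(
                symbol=row["symbol"].strip(),
                immune_class=row["immune_class"].strip(),
                aliases=aliases,
            )
        )
    return GeneCatalog(records)
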